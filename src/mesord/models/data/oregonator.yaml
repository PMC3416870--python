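# Oregonator scheme for the Belousov-Zhabotinsky reaction, copy-count
# representation with the pool species A, B absorbed into effective
# unimolecular constants (c1 = k1*A etc.).
#
# Species: X = HBrO2 (activator), Y = Br- (inhibitor), Z = oxidized
# catalyst (recovery variable), plus helper species S1, S2 that realize
# the fractional-stoichiometry step Z -> f Y with f = 3/2 as
#   Z -> S1 (rate c5),  S1 + S1 -> S2 + 2Y (fast),  S2 -> Y (fast).
#
# In Tyson-Fife scaling this set has eps = c5/c3 = 0.1 and
# q = 2 c1 c4/(c2 c3) = 0.002, inside the oscillatory regime used for
# classic spiral-wave studies (Jahnke, Skaggs & Winfree, J. Phys. Chem.
# 93, 1989); X and Z diffuse, Y is spatially pinned.
c1: 0.5        # Y -> X            (effective, A absorbed)
c2: 100.0      # X + Y -> 0
c3: 1.0        # X -> 2X + Z       (effective, B absorbed)
c4: 0.2        # X + X -> 0
c5: 0.1        # Z -> S1 (the fractional Z -> f Y step)
f: 1.5         # stoichiometric (bifurcation) factor, realized exactly
helper_separation: 1000.0   # k_a = k_b = separation * max(c1..c5)
min_helper_separation: 100.0
diffusivity_x: 1.0
diffusivity_z: 0.6
nx: 128
ny: 128
lambda: 1.0
# Jahnke-type wedge induction: activator overdensity in a polar wedge,
# catalyst proportional to the polar angle, Y at its local dynamic
# equilibrium f c5 Z / (c1 + c2 X)
wedge_angle: 0.5          # radians, wedge is 0 <= theta < wedge_angle
x_wedge_fraction: 0.8     # X in wedge, units of X0 = c3/(2 c4)
z_angle_scale: 8.0        # Z(theta) = Z0 * theta/(z_angle_scale*pi*f)
z_floor_fraction: 0.001   # small uniform Z offset, units of Z0
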