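# Single-pool intracellular Ca2+ wave model (IP3-receptor release, SERCA
# reuptake, membrane leak), after the Xenopus oocyte model of Atri,
# Amundson, Clapham & Sneyd (Biophys. J. 65, 1993).
#
# Species: c = cytosolic Ca2+, n = open IP3-receptor channels per
# subvolume, p = IP3.  Rate constants are in uM and seconds and are
# converted to per-subvolume copy counts with the concentration base
# counts_per_uM = 602.2 * lambda^3 (lambda in um).
#
# This is a synthetic Atri-type parameter set: several constants (b,
# k_act, gamma, k_inhib) are shifted from Atri's printed values so that
# the (c, n) phase plane with mu(p) = p/(k_mu + p) exhibits exactly three
# fixed points (stable rest, saddle, unstable focus) and an excitable
# excursion, the structure required of the model here.
k_flux: 16.2       # uM/s, maximal channel flux at all channels open
b: 0.03            # baseline channel activation (dimensionless)
k_act: 1.2         # uM, Ca2+ activation half-saturation
k_mu: 0.7          # uM, IP3 half-saturation of mu(p)
gamma: 2.6         # uM/s, SERCA pump maximal rate
k_gamma: 0.1       # uM, pump half-saturation
k_inhib: 1.5       # uM, cooperative Ca2+ inhibition constant (Hill 2)
tau_h: 2.0         # s, channel inactivation relaxation time
beta: 0.05         # uM/s, membrane leak (zeroth order)
k_p: 0.005         # 1/s, IP3 breakdown
n_channels: 20     # IP3R channels per subvolume at Omega = 1
p_background: 0.855   # uM, resting IP3 (mu = 0.55)
diffusivity_ca: 20.0  # um^2/s
diffusivity_ip3: 300.0
domain_length: 250.0  # um
nx: 128
ny: 128
# spiral induction: Ca2+ overdensity rectangle plus refractory right half
# (elevated Ca2+, all channels shut)
rect: [0.25, 0.45, 0.48, 0.55]
c_perturb: 1.0        # uM inside the rectangle
c_refractory: 0.8     # uM in the right half
n_refractory: 0.0     # open channels in the right half
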