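# Gray-Scott excitable medium, per-subvolume copy-count representation.
#
# Reaction scheme: U + 2V -> 3V (cubic autocatalysis), V -> 0, 0 -> U,
# U -> 0.  The substrate U plays the inhibitor role and is spatially
# pinned; the activator V diffuses.  Rates are in 1/time at system size
# Omega = 1; counts are dimensionless.
#
# The excitability parameter a = k1 k3^2 / (4 k2^2 k4) controls how many
# homogeneous states the activator nullcline admits (a < 1: one, a = 1:
# two, a > 1: three).  This set sits on the excitable side of the
# saddle-node curve (a = 1.5625) of the one-diffusing-species Gray-Scott
# variant studied by Mazin et al. (Math. Comput. Simul. 40, 1996) and in
# Pearson-type pattern surveys; free wave ends then curl into spike
# spiral waves on a 128x128 domain.
k1: 1.0        # autocatalysis U + 2V -> 3V (order 3, scales as Omega^-2)
k2: 1.0        # activator decay V -> 0
k3: 0.5        # substrate feed 0 -> U (order 0, scales as Omega)
k4: 0.04       # substrate decay U -> 0
diffusivity_v: 2.0
nx: 128
ny: 128
lambda: 1.0
# spiral induction protocol: super-threshold activator rectangle in the
# left half plus a substrate-depleted (refractory) right half
rect: [0.25, 0.45, 0.48, 0.55]   # x0, x1, y0, y1 as fractions of L
v_perturb: 2.0
u_refractory: 0.04
v_refractory: 0.0
n_fixed_points: 3
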