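# Two-level Rabi oscillation, decoupled from the mode bank (grid solver).
# H_S = (Omega/2) sigma_x with Omega = 2; w_S = |0><0|; exact answer
# <sigma_z>(t) = cos(Omega t).

[model.h_s]
real = [[0.0, 1.0], [1.0, 0.0]]

[model.chi]
real = [[0.0, 0.0], [0.0, 0.0]]

[model.banks.phonon]
omega = [1.0]
coupling = [0.0]

[statmech]
beta = "inf"
regime = "zero_point"
seed = 1

[statmech.w_s]
real = [[1.0, 0.0], [0.0, 0.0]]

[dynamics]
solver = "grid"
dt = 0.002
n_steps = 15708      # ten Rabi periods
record_stride = 157
grid_points = [32, 32]
extent_sigmas = 7.5

[[observables]]
name = "sigma_z"
matrix = { real = [[1.0, 0.0], [0.0, -1.0]] }

[output]
directory = "rabi_out"
formats = ["csv"]
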