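# Spin-boson demo: two-level system (gap 2) weakly coupled to one thermal
# mode, adiabatic-basis trajectory ensemble with nonadiabatic hops.

[model.h_s]
real = [[0.0, 1.0], [1.0, 0.0]]

[model.chi]
real = [[1.0, 0.0], [0.0, -1.0]]

[model.banks.phonon]
omega = [1.0]
coupling = [0.2]

[statmech]
beta = 1.0
regime = "thermal_wigner"
n_samples = 2000
seed = 1

[statmech.w_s]
real = [[1.0, 0.0], [0.0, 0.0]]

[dynamics]
solver = "trajectory"
dt = 0.01
n_steps = 500
record_stride = 25
hop_mode = "nonadiabatic"

[[observables]]
name = "sigma_z"
matrix = { real = [[1.0, 0.0], [0.0, -1.0]] }

[output]
directory = "spin_boson_out"
formats = ["csv", "hdf5"]
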