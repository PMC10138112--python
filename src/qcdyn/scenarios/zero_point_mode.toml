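# One uncoupled harmonic mode (omega = 1) thermostatted at its zero-point
# target T = omega/2; the long-run average of P^2 approaches omega/2 = 0.5.

[model.h_s]
real = [[0.0]]

[model.chi]
real = [[0.0]]

[model.banks.phonon]
omega = [1.0]
coupling = [0.0]

[statmech]
beta = "inf"
regime = "zero_point"
n_samples = 48
seed = 1

[thermostat]
enabled = true
mode = "zero_point"
chain_length = 2

[dynamics]
solver = "classical"
dt = 0.02
n_steps = 50000
record_stride = 5

[[observables]]
name = "p_squared"
matrix = { real = [[0.0]] }
classical = "p_squared"

[output]
directory = "zero_point_out"
formats = ["csv"]
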