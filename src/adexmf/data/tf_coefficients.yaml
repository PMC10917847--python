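# Effective-threshold polynomial coefficients for the population transfer
# functions, in volts.  Second-order polynomial in the normalized membrane
# moments (mean potential, potential fluctuation amplitude, normalized
# autocorrelation time).  Order of terms:
#   P0, P1*V, P2*S, P3*T, P4*V^2, P5*S^2, P6*T^2, P7*V*S, P8*V*T, P9*S*T
# where V, S, T are the normalized first, second and timescale moments.
# Values fitted on regular-spiking (excitatory) and fast-spiking (inhibitory)
# adaptive exponential integrate-and-fire populations.
excitatory: [-0.0498, 0.00506, -0.025, 0.0014, -0.00041, 0.0105, -0.036, 0.0074, 0.0012, -0.0407]
inhibitory: [-0.0514, 0.004, -0.0083, 0.0002, -0.0005, 0.0014, -0.0146, 0.0045, 0.0028, -0.0153]
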