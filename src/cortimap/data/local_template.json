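{
  "comment": "Layered-microcircuit template for a 1 mm^2 patch of early sensory cortex: pairwise connection probabilities C[target][source] between the eight populations, template population sizes, the Gaussian width of the underlying distance-dependent connection probability, its pair-averaged peak C0, and the template's disk-averaged probability with one neuron fixed at the center of the 1 mm^2 disk.",
  "version": 1,
  "populations": ["23E", "23I", "4E", "4I", "5E", "5I", "6E", "6I"],
  "connection_probabilities": [
    [0.101, 0.169, 0.044, 0.082, 0.032, 0.0,    0.008, 0.0],
    [0.135, 0.137, 0.032, 0.052, 0.075, 0.0,    0.004, 0.0],
    [0.008, 0.006, 0.050, 0.135, 0.007, 0.0003, 0.045, 0.0],
    [0.069, 0.003, 0.079, 0.160, 0.003, 0.0,    0.106, 0.0],
    [0.100, 0.062, 0.051, 0.006, 0.083, 0.373,  0.020, 0.0],
    [0.055, 0.027, 0.026, 0.002, 0.060, 0.316,  0.009, 0.0],
    [0.016, 0.007, 0.021, 0.017, 0.057, 0.020,  0.040, 0.225],
    [0.036, 0.001, 0.003, 0.001, 0.028, 0.008,  0.066, 0.144]
  ],
  "population_sizes": [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948],
  "sigma_mm": 0.297,
  "C0": 0.143,
  "Cbar_center_R0": 0.066
}
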