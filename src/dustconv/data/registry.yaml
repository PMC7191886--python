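# Published conversion-function coefficients, transcribed from the
# study's results table: sample size n, Pearson R, adjusted R²,
# intercept C0 ± se, exponent k ± se, and the range of the standard
# error of the fitted regression mean s_Fit(ln c_R).
#
# The sha256 field is a transcription checksum over the canonical JSON
# serialisation of the entries list; the loader refuses a file whose
# digest does not match.
#
# Note: the study's summary text quotes exponents from 0.454 to 0.946,
# but the smallest exponent actually printed in the table is 0.500
# (group 1); 0.500 is the true table minimum.
version: "1"
sha256: "cf221577ac01fa0389173e1e75111d9d3dd36f857e7f05d6ae77592fe720368c"
entries:
  - {id: "0", name: "Entire data set", n: 15120, R: 0.765, adj_R2: 0.585, C0: -0.990, se_C0: 0.006, k: 0.594, se_k: 0.004, s_fit_min: 0.0092, s_fit_max: 0.0400}
  - {id: "1", name: "Surface treatment", n: 805, R: 0.735, adj_R2: 0.540, C0: -1.046, se_C0: 0.024, k: 0.500, se_k: 0.016, s_fit_min: 0.0427, s_fit_max: 0.1396}
  - {id: "2", name: "High temperature processing", n: 2974, R: 0.818, adj_R2: 0.668, C0: -0.751, se_C0: 0.011, k: 0.729, se_k: 0.009, s_fit_min: 0.0184, s_fit_max: 0.0708}
  - {id: "3", name: "Filling/transport/storage", n: 3473, R: 0.791, adj_R2: 0.626, C0: -1.093, se_C0: 0.012, k: 0.586, se_k: 0.008, s_fit_min: 0.0192, s_fit_max: 0.0698}
  - {id: "4", name: "Machining/abrasive techniques", n: 4640, R: 0.776, adj_R2: 0.602, C0: -1.031, se_C0: 0.016, k: 0.578, se_k: 0.013, s_fit_min: 0.0169, s_fit_max: 0.0553}
  - {id: "5", name: "Forming", n: 1348, R: 0.774, adj_R2: 0.599, C0: -1.037, se_C0: 0.011, k: 0.579, se_k: 0.007, s_fit_min: 0.0272, s_fit_max: 0.1071}
  - {id: "6", name: "Others", n: 1880, R: 0.768, adj_R2: 0.590, C0: -1.100, se_C0: 0.016, k: 0.593, se_k: 0.011, s_fit_min: 0.0275, s_fit_max: 0.1106}
  - {id: "A", name: "Mineral-dominated", n: 9315, R: 0.785, adj_R2: 0.616, C0: -1.058, se_C0: 0.007, k: 0.581, se_k: 0.005, s_fit_min: 0.0119, s_fit_max: 0.0512}
  - {id: "B", name: "Metal-dominated", n: 5269, R: 0.748, adj_R2: 0.559, C0: -0.851, se_C0: 0.010, k: 0.614, se_k: 0.008, s_fit_min: 0.0146, s_fit_max: 0.0531}
  - {id: "C", name: "Fiber-dominated", n: 536, R: 0.761, adj_R2: 0.578, C0: -1.176, se_C0: 0.031, k: 0.614, se_k: 0.023, s_fit_min: 0.0543, s_fit_max: 0.1977}
  - {id: "1-A", name: "Surface treatment - mineral-dominated", n: 540, R: 0.756, adj_R2: 0.571, C0: -1.043, se_C0: 0.059, k: 0.512, se_k: 0.038, s_fit_min: 0.0549, s_fit_max: 0.1660}
  - {id: "2-B", name: "High temperature processing - metal-dominated", n: 2265, R: 0.840, adj_R2: 0.706, C0: -0.687, se_C0: 0.013, k: 0.758, se_k: 0.010, s_fit_min: 0.0268, s_fit_max: 0.0961}
  - {id: "4-A", name: "Machining/abrasive techniques - mineral-dominated", n: 2632, R: 0.802, adj_R2: 0.643, C0: -1.015, se_C0: 0.026, k: 0.595, se_k: 0.017, s_fit_min: 0.0227, s_fit_max: 0.0732}
  - {id: "6-B", name: "Other - metal-dominated", n: 331, R: 0.779, adj_R2: 0.608, C0: -0.898, se_C0: 0.068, k: 0.618, se_k: 0.054, s_fit_min: 0.0608, s_fit_max: 0.1910}
  - {id: "alpha", name: "Soldering", n: 34, R: 0.917, adj_R2: 0.835, C0: -0.559, se_C0: 0.074, k: 0.946, se_k: 0.073, s_fit_min: 0.1634, s_fit_max: 0.4417}
  - {id: "beta", name: "Casting (metalworking)", n: 77, R: 0.877, adj_R2: 0.767, C0: -0.430, se_C0: 0.058, k: 0.913, se_k: 0.049, s_fit_min: 0.0857, s_fit_max: 0.2322}
  - {id: "gamma", name: "Welding", n: 1126, R: 0.875, adj_R2: 0.766, C0: -0.601, se_C0: 0.018, k: 0.803, se_k: 0.014, s_fit_min: 0.0297, s_fit_max: 0.1005}
  - {id: "delta", name: "High temperature cutting", n: 176, R: 0.897, adj_R2: 0.803, C0: -0.716, se_C0: 0.028, k: 0.750, se_k: 0.028, s_fit_min: 0.0832, s_fit_max: 0.2832}
  - {id: "epsilon", name: "Blasting", n: 57, R: 0.907, adj_R2: 0.819, C0: -1.107, se_C0: 0.080, k: 0.724, se_k: 0.045, s_fit_min: 0.1847, s_fit_max: 0.4479}
  - {id: "zeta", name: "Chiseling, embossing", n: 41, R: 0.912, adj_R2: 0.827, C0: -1.264, se_C0: 0.111, k: 0.695, se_k: 0.050, s_fit_min: 0.2113, s_fit_max: 0.4946}
  - {id: "eta", name: "Wire drawing", n: 61, R: 0.859, adj_R2: 0.733, C0: -1.028, se_C0: 0.087, k: 0.695, se_k: 0.054, s_fit_min: 0.1387, s_fit_max: 0.4000}
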