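{
  "version": 1,
  "description": "Two-cell leech heart-interneuron half-center oscillator: gating constants, reversal potentials, synapse kinetics and the canonical free-parameter set. All values in SI units (volts, seconds, siemens, farads, amperes).",
  "capacitance_F": 5e-10,
  "reversal_potentials_V": {
    "Na": 0.045,
    "Ca": 0.135,
    "h": -0.021,
    "K": -0.07,
    "Syn": -0.0625
  },
  "channels": {
    "Na": {
      "x": 3, "y": 1, "E": "Na",
      "activation":   {"form": "sigmoid", "a": -150.0, "b": 0.029,
                       "tau_form": "const", "tau_c": 0.0001},
      "inactivation": {"form": "sigmoid", "a": 500.0, "b": 0.030,
                       "tau_form": "na_inact",
                       "tau_c": 0.004, "tau_d": 0.006, "tau_A": 500.0, "tau_b": 0.028,
                       "tau_e": 0.01, "tau_F": 300.0, "tau_g": 0.027}
    },
    "P": {
      "x": 1, "y": 0, "E": "Na",
      "activation": {"form": "sigmoid", "a": -120.0, "b": 0.039,
                     "tau_form": "sigmoid", "tau_A": 400.0, "tau_b": 0.057,
                     "tau_c": 0.01, "tau_d": 0.2}
    },
    "CaF": {
      "x": 2, "y": 1, "E": "Ca",
      "activation":   {"form": "sigmoid", "a": -600.0, "b": 0.0467,
                       "tau_form": "cosh", "tau_c": 0.011, "tau_d": 0.024,
                       "tau_A": 330.0, "tau_b": 0.0467},
      "inactivation": {"form": "sigmoid", "a": 350.0, "b": 0.0555,
                       "tau_form": "sigmoid", "tau_A": 270.0, "tau_b": 0.055,
                       "tau_c": 0.06, "tau_d": 0.31}
    },
    "CaS": {
      "x": 2, "y": 1, "E": "Ca",
      "activation":   {"form": "sigmoid", "a": -420.0, "b": 0.0472,
                       "tau_form": "sigmoid", "tau_A": -400.0, "tau_b": 0.0487,
                       "tau_c": 0.005, "tau_d": 0.134},
      "inactivation": {"form": "sigmoid", "a": 360.0, "b": 0.055,
                       "tau_form": "sigmoid", "tau_A": -250.0, "tau_b": 0.043,
                       "tau_c": 0.2, "tau_d": 5.25}
    },
    "h": {
      "x": 2, "y": 0, "E": "h",
      "activation": {"form": "h_double", "a": 180.0, "b": 0.047, "a2": 500.0,
                     "tau_form": "sigmoid", "tau_A": -100.0, "tau_b": 0.073,
                     "tau_c": 0.7, "tau_d": 1.7}
    },
    "K1": {
      "x": 2, "y": 1, "E": "K",
      "activation":   {"form": "sigmoid", "a": -143.0, "b": 0.021,
                       "tau_form": "sigmoid", "tau_A": 150.0, "tau_b": 0.016,
                       "tau_c": 0.001, "tau_d": 0.011},
      "inactivation": {"form": "sigmoid", "a": 111.0, "b": 0.028,
                       "tau_form": "sigmoid", "tau_A": -143.0, "tau_b": 0.013,
                       "tau_c": 0.5, "tau_d": 0.2}
    },
    "K2": {
      "x": 2, "y": 0, "E": "K",
      "activation": {"form": "sigmoid", "a": -83.0, "b": 0.02,
                     "tau_form": "sigmoid", "tau_A": 200.0, "tau_b": 0.035,
                     "tau_c": 0.057, "tau_d": 0.043}
    },
    "KA": {
      "x": 2, "y": 1, "E": "K",
      "activation":   {"form": "sigmoid", "a": -130.0, "b": 0.044,
                       "tau_form": "sigmoid", "tau_A": 200.0, "tau_b": 0.03,
                       "tau_c": 0.005, "tau_d": 0.011},
      "inactivation": {"form": "sigmoid", "a": 160.0, "b": 0.063,
                       "tau_form": "sigmoid", "tau_A": -300.0, "tau_b": 0.055,
                       "tau_c": 0.026, "tau_d": 0.0085}
    }
  },
  "synapse": {
    "E": "Syn",
    "tau_rise_s": 0.002,
    "tau_decay_s": 0.011,
    "M_inf": {"base": 0.1, "amp": 0.9, "a": -1000.0, "b": 0.04},
    "tau_M_s": 0.2,
    "graded_pool": {
      "buffer_rate_per_s": 10.0,
      "saturation_C3": 1e-32,
      "threshold_A": 1e-11
    }
  },
  "canonical_gbar_nS": {
    "Na": 200.0, "P": 7.0, "CaF": 5.0, "CaS": 3.2, "h": 4.0,
    "K1": 100.0, "K2": 80.0, "KA": 80.0, "Leak": 8.0,
    "SynS": 60.0, "SynG": 30.0
  },
  "canonical_E_Leak_V": -0.06
}
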