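{
  "_comment": "Default model parameters. Units: rates A in ms^-1, voltage sensitivities B in mV^-1, conductance g in uS. The candidate set is a literature-plausible hERG Hodgkin-Huxley parameterisation (slow activation, fast inactivation); the ground-truth set parameterises a C1<=>C2<=>O activation chain whose tail deactivation shows two well-separated time constants. Both are defaults and can be replaced by files with the same schema.",
  "candidate": {
    "g_uS": 1.0,
    "activation_A_alpha_per_ms": 2.26e-4,
    "activation_B_alpha_per_mV": 0.0699,
    "activation_A_beta_per_ms": 3.45e-5,
    "activation_B_beta_per_mV": -0.05462,
    "inactivation_A_alpha_per_ms": 5.15e-3,
    "inactivation_B_alpha_per_mV": -0.03158,
    "inactivation_A_beta_per_ms": 0.0873,
    "inactivation_B_beta_per_mV": 0.00891
  },
  "ground_truth": {
    "g_uS": 1.0,
    "c1_c2_A_alpha_per_ms": 2.26e-4,
    "c1_c2_B_alpha_per_mV": 0.0699,
    "c1_c2_A_beta_per_ms": 3.45e-5,
    "c1_c2_B_beta_per_mV": -0.05462,
    "c2_o_A_alpha_per_ms": 5.0e-3,
    "c2_o_B_alpha_per_mV": 0.03,
    "c2_o_A_beta_per_ms": 4.0e-3,
    "c2_o_B_beta_per_mV": -0.02,
    "inactivation_A_alpha_per_ms": 5.15e-3,
    "inactivation_B_alpha_per_mV": -0.03158,
    "inactivation_A_beta_per_ms": 0.0873,
    "inactivation_B_beta_per_mV": 0.00891
  }
}
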