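{
  "comment": "Generative parameter sets for the three Kv1.1 channel populations (homomeric WT, homomeric P403A, 1:1 co-expressed heteromer treated as a single species). Voltages in mV, activation/deactivation taus in ms, inactivation/recovery taus in s. tau-law slopes (k_tau) and frac_fast are generator defaults, not measured values. g_max is null and is calibrated at load time so the steady IV current at +20 mV equals amplitude_at_plus20 (display units). E_rev is null and is computed from the recording solutions (2.8 mM K out / 132 mM K in, 293.15 K).",
  "solutions": {"K_out_mM": 2.8, "K_in_mM": 132.0, "temperature_K": 293.15},
  "species": [
    {
      "name": "Kv1.1-WT",
      "activation": {"V_half": -21.5, "k": 10.0},
      "act_tau": {"tau_at_Vhalf": 9.4, "k_tau": -25.0},
      "deact_tau": {"tau_at_Vhalf": 41.5, "k_tau": 25.0},
      "inact": {"tau_fast": 4.9, "tau_slow": 37.4, "frac_fast": 0.3, "tau_recovery": 3.4},
      "amplitude_at_plus20": 2.1,
      "tail_V": -50.0,
      "g_max": null,
      "E_rev": null
    },
    {
      "name": "P403A",
      "activation": {"V_half": 7.8, "k": 9.0},
      "act_tau": {"tau_at_Vhalf": 31.7, "k_tau": -25.0},
      "deact_tau": {"tau_at_Vhalf": 47.2, "k_tau": 25.0},
      "inact": {"tau_fast": 5.8, "tau_slow": 42.1, "frac_fast": 0.3, "tau_recovery": 2.2},
      "amplitude_at_plus20": 0.4,
      "tail_V": -30.0,
      "g_max": null,
      "E_rev": null
    },
    {
      "name": "Kv1.1-WT+P403A",
      "activation": {"V_half": -4.3, "k": 12.0},
      "act_tau": {"tau_at_Vhalf": 14.7, "k_tau": -25.0},
      "deact_tau": {"tau_at_Vhalf": 41.5, "k_tau": 25.0},
      "inact": {"tau_fast": 5.8, "tau_slow": 40.2, "frac_fast": 0.3, "tau_recovery": 2.8},
      "amplitude_at_plus20": 0.55,
      "tail_V": -30.0,
      "g_max": null,
      "E_rev": null
    }
  ]
}
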