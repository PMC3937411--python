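{
  "fig1_caseA": {
    "cross_cov": [
      [
        0.25
      ],
      [
        0.5
      ],
      [
        0.25
      ]
    ],
    "mean_resp_cov": [
      [
        0.25,
        0.5,
        0.25
      ],
      [
        0.5,
        1.0,
        0.5
      ],
      [
        0.25,
        0.5,
        0.25
      ]
    ],
    "noise_corr": [
      0.0,
      0.0,
      0.0
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        1.0
      ],
      [
        2.0
      ],
      [
        1.0
      ]
    ],
    "stim_cov": [
      [
        0.25
      ]
    ],
    "stimulus_means": [
      [
        1.0,
        2.0,
        3.0
      ],
      [
        2.0,
        4.0,
        4.0
      ]
    ]
  },
  "fig1_caseB": {
    "cross_cov": [
      [
        0.25
      ],
      [
        0.5
      ],
      [
        0.25
      ]
    ],
    "mean_resp_cov": [
      [
        0.25,
        0.5,
        0.25
      ],
      [
        0.5,
        1.0,
        0.5
      ],
      [
        0.25,
        0.5,
        0.25
      ]
    ],
    "noise_corr": [
      0.4,
      0.4,
      0.4
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        1.0
      ],
      [
        2.0
      ],
      [
        1.0
      ]
    ],
    "stim_cov": [
      [
        0.25
      ]
    ],
    "stimulus_means": [
      [
        1.0,
        2.0,
        3.0
      ],
      [
        2.0,
        4.0,
        4.0
      ]
    ]
  },
  "fig1_caseC": {
    "cross_cov": [
      [
        0.25
      ],
      [
        0.5
      ],
      [
        0.25
      ]
    ],
    "mean_resp_cov": [
      [
        0.25,
        0.5,
        0.25
      ],
      [
        0.5,
        1.0,
        0.5
      ],
      [
        0.25,
        0.5,
        0.25
      ]
    ],
    "noise_corr": [
      -0.3,
      -0.3,
      -0.3
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        1.0
      ],
      [
        2.0
      ],
      [
        1.0
      ]
    ],
    "stim_cov": [
      [
        0.25
      ]
    ],
    "stimulus_means": [
      [
        1.0,
        2.0,
        3.0
      ],
      [
        2.0,
        4.0,
        4.0
      ]
    ]
  },
  "fig1_caseD": {
    "cross_cov": [
      [
        0.25
      ],
      [
        0.5
      ],
      [
        0.25
      ]
    ],
    "mean_resp_cov": [
      [
        0.25,
        0.5,
        0.25
      ],
      [
        0.5,
        1.0,
        0.5
      ],
      [
        0.25,
        0.5,
        0.25
      ]
    ],
    "noise_corr": [
      0.9,
      0.0,
      0.0
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        1.0
      ],
      [
        2.0
      ],
      [
        1.0
      ]
    ],
    "stim_cov": [
      [
        0.25
      ]
    ],
    "stimulus_means": [
      [
        1.0,
        2.0,
        3.0
      ],
      [
        2.0,
        4.0,
        4.0
      ]
    ]
  },
  "fig2": {
    "cross_cov": [
      [
        1.0
      ],
      [
        0.8
      ],
      [
        -0.5
      ]
    ],
    "mean_resp_cov": [
      [
        1.0,
        0.4,
        0.2
      ],
      [
        0.4,
        1.0,
        0.4
      ],
      [
        0.2,
        0.4,
        1.0
      ]
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        1.0
      ],
      [
        0.8
      ],
      [
        -0.5
      ]
    ],
    "slice_constraint": "rho13 == rho23",
    "stim_cov": [
      [
        1.0
      ]
    ]
  },
  "fig3_A": {
    "cross_cov": [
      [
        1.6
      ],
      [
        1.6
      ],
      [
        1.6
      ]
    ],
    "mean_resp_cov": [
      [
        1.0,
        0.3,
        0.3
      ],
      [
        0.3,
        1.0,
        0.3
      ],
      [
        0.3,
        0.3,
        1.0
      ]
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        1.6
      ],
      [
        1.6
      ],
      [
        1.6
      ]
    ],
    "stim_cov": [
      [
        1.0
      ]
    ]
  },
  "fig3_B": {
    "cross_cov": [
      [
        3.3000000000000003
      ],
      [
        1.8
      ],
      [
        1.5
      ]
    ],
    "mean_resp_cov": [
      [
        1.0,
        0.2,
        0.1
      ],
      [
        0.2,
        1.0,
        0.2
      ],
      [
        0.1,
        0.2,
        1.0
      ]
    ],
    "noise_vars": [
      1.0,
      1.0,
      1.0
    ],
    "sensitivities": [
      [
        3.3000000000000003
      ],
      [
        1.8
      ],
      [
        1.5
      ]
    ],
    "stim_cov": [
      [
        4.0
      ]
    ]
  }
}
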