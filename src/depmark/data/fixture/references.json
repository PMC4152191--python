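{
  "generator_seed": 5,
  "deterministic": {
    "absenteeism_blue": {
      "cost_lpt": 4876.413627154317,
      "cost_turnover": 1613.9466384565826,
      "cost_service": 629.1805679147869,
      "cost_antidepressant": 90.027083003779,
      "qalys": 0.7096442553992479,
      "cost_total": 7209.567916529466
    },
    "absenteeism_white": {
      "cost_lpt": 6841.027017926336,
      "cost_turnover": 2536.2100031794607,
      "cost_service": 387.1184611820168,
      "cost_antidepressant": 109.69216824204895,
      "qalys": 0.713154671689712,
      "cost_total": 9874.047650529863
    },
    "presenteeism_blue": {
      "cost_lpt": 4046.2998184075345,
      "cost_turnover": 1416.0113630832163,
      "cost_service": 667.5885804927624,
      "cost_antidepressant": 95.5227411863373,
      "qalys": 0.7238856313419683,
      "cost_total": 6225.42250316985
    },
    "presenteeism_white": {
      "cost_lpt": 4749.140825262359,
      "cost_turnover": 2115.289992041753,
      "cost_service": 420.3527037731398,
      "cost_antidepressant": 119.10927565297258,
      "qalys": 0.736924886746103,
      "cost_total": 7403.892796730224
    }
  },
  "psa": {
    "absenteeism_blue": {
      "n_iterations": 1000,
      "seed": 0,
      "summaries": {
        "cost_lpt": [
          4866.997378535366,
          3414.105333329913,
          6711.0242525832355
        ],
        "cost_turnover": [
          1624.9597406477894,
          957.2697144520206,
          2518.022995018374
        ],
        "cost_service": [
          631.6648520401467,
          477.8875974104372,
          812.0257376814907
        ],
        "cost_antidepressant": [
          90.49122452930672,
          58.44201284420544,
          126.71097975451305
        ],
        "cost_total": [
          7214.113195752609,
          5529.592755429788,
          9329.328476268685
        ],
        "qalys": [
          0.7097784138850102,
          0.6738499167430083,
          0.7456977751402964
        ]
      }
    },
    "absenteeism_white": {
      "n_iterations": 1000,
      "seed": 0,
      "summaries": {
        "cost_lpt": [
          6828.757761156375,
          4813.452959504737,
          9414.557167012636
        ],
        "cost_turnover": [
          2554.064041165347,
          1506.9597358096423,
          3955.327712061524
        ],
        "cost_service": [
          389.1058414139439,
          278.6537248555382,
          525.9651533155707
        ],
        "cost_antidepressant": [
          110.2690950467664,
          70.41502143120861,
          155.36684872459912
        ],
        "cost_total": [
          9882.196738782432,
          7461.307680791166,
          12921.754046788605
        ],
        "qalys": [
          0.7134280199199587,
          0.6773315465860168,
          0.7489577109122205
        ]
      }
    },
    "presenteeism_blue": {
      "n_iterations": 1000,
      "seed": 0,
      "summaries": {
        "cost_lpt": [
          4021.66474143002,
          2790.56663474536,
          5709.385347638791
        ],
        "cost_turnover": [
          1425.531253055019,
          829.6087514557331,
          2190.0022502088323
        ],
        "cost_service": [
          670.3845037295605,
          507.7929519542342,
          860.6264705482434
        ],
        "cost_antidepressant": [
          95.15551361156912,
          59.0349599534269,
          139.45454377802577
        ],
        "cost_total": [
          6212.736011826169,
          4732.501866417549,
          8063.4836348182125
        ],
        "qalys": [
          0.723889420533045,
          0.6852926870904581,
          0.7613840975347916
        ]
      }
    },
    "presenteeism_white": {
      "n_iterations": 1000,
      "seed": 0,
      "summaries": {
        "cost_lpt": [
          4723.162779881703,
          3281.6753974580606,
          6680.905835135167
        ],
        "cost_turnover": [
          2130.0830759945466,
          1257.9397485078503,
          3282.2411677544023
        ],
        "cost_service": [
          422.7480008110191,
          305.08390889204026,
          570.0642431131862
        ],
        "cost_antidepressant": [
          118.6900606885417,
          73.96859248353091,
          173.95597934239626
        ],
        "cost_total": [
          7394.683917375811,
          5535.914064136897,
          9660.396174201604
        ],
        "qalys": [
          0.7371015131091346,
          0.6962642832752154,
          0.7739292983128784
        ]
      }
    }
  }
}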