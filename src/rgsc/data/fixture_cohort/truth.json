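{
 "config": {
  "c_mean": 19.0,
  "c_min": 5,
  "c_sd": 3.9,
  "n_participants": 33,
  "noise_sd": 1.0,
  "p_polar_ideal": 0.55,
  "seed": 20180101,
  "target_rho": 0.5
 },
 "distress": {
  "p01": 0.16326840588113012,
  "p02": 0.5028488240581541,
  "p03": 0.23872702737020246,
  "p04": 0.18608182182570343,
  "p05": 0.22120041818516656,
  "p06": 0.42949828067625906,
  "p07": 0.5079076899937992,
  "p08": 0.9554834610316455,
  "p09": 0.27550480030257185,
  "p10": 0.8362855627585294,
  "p11": 0.1983871426961803,
  "p12": 0.24332958639651514,
  "p13": 0.4784550711506236,
  "p14": 0.24471354397585943,
  "p15": 0.24130835089114522,
  "p16": 0.08705679321889448,
  "p17": 0.9658769737304902,
  "p18": 0.2496280032864212,
  "p19": 0.9711304285131646,
  "p20": 0.14692475273172179,
  "p21": 0.5461601282294821,
  "p22": 0.08444494532882374,
  "p23": 0.012447517926739482,
  "p24": 0.10065602274319885,
  "p25": 0.823376289643416,
  "p26": 0.03347972834102508,
  "p27": 0.630557229895057,
  "p28": 0.22099523153513212,
  "p29": 0.42123619578109284,
  "p30": 0.7023898352036114,
  "p31": 0.7696959612707404,
  "p32": 0.025581632408300803,
  "p33": 0.4856514753671828
 },
 "orientations": {
  "p01": [
   1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   -1,
   1
  ],
  "p02": [
   -1,
   1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   -1,
   -1,
   1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   1
  ],
  "p03": [
   -1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   1
  ],
  "p04": [
   1,
   -1,
   -1,
   -1,
   -1,
   -1,
   -1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1
  ],
  "p05": [
   -1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1
  ],
  "p06": [
   -1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   -1
  ],
  "p07": [
   -1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   1
  ],
  "p08": [
   1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   -1,
   -1,
   1,
   1,
   -1
  ],
  "p09": [
   1,
   -1,
   1,
   -1,
   -1,
   -1,
   -1,
   1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   1
  ],
  "p10": [
   -1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   -1
  ],
  "p11": [
   -1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   -1
  ],
  "p12": [
   -1,
   1,
   1,
   1,
   1,
   1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   1,
   1,
   1,
   -1
  ],
  "p13": [
   -1,
   1,
   -1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   1
  ],
  "p14": [
   -1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   -1
  ],
  "p15": [
   1,
   -1,
   1,
   1,
   -1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   1
  ],
  "p16": [
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   -1
  ],
  "p17": [
   1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   1
  ],
  "p18": [
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   1,
   -1,
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   -1,
   1
  ],
  "p19": [
   1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   1,
   -1,
   1
  ],
  "p20": [
   -1,
   -1,
   1,
   1,
   -1,
   -1,
   -1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1
  ],
  "p21": [
   -1,
   -1,
   1,
   1,
   -1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1
  ],
  "p22": [
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   -1
  ],
  "p23": [
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   1
  ],
  "p24": [
   -1,
   -1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   1,
   -1,
   -1
  ],
  "p25": [
   1,
   1,
   1,
   1,
   -1,
   1,
   1,
   1,
   -1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   -1,
   -1
  ],
  "p26": [
   1,
   1,
   -1,
   -1,
   -1,
   1,
   1,
   -1,
   -1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   1,
   -1
  ],
  "p27": [
   1,
   1,
   1,
   1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   -1
  ],
  "p28": [
   1,
   -1,
   -1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   -1
  ],
  "p29": [
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   -1,
   -1,
   1
  ],
  "p30": [
   -1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   -1,
   -1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   1
  ],
  "p31": [
   1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   -1,
   -1,
   1,
   1,
   1
  ],
  "p32": [
   1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   -1,
   1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   -1,
   -1
  ],
  "p33": [
   1,
   1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   1,
   -1,
   -1,
   1,
   1,
   1,
   1,
   -1,
   1,
   1,
   -1,
   1,
   -1
  ]
 }
}
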