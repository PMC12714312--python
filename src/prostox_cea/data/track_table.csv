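track,weight_pct,cost_t0,cost_y1,cost_y2,cost_y3,cost_y4,cost_y5,lifetime_cost,lifetime_qalys
T1,0.00,20670,0,0,0,0,0,24170,0.00
T2,9.48,42643,276,274,271,266,260,93306,11.28
T3,9.24,97782,270,287,274,260,247,144030,11.59
T4,73.26,20670,2135,2061,1987,1911,1836,65700,11.68
T5,0.00,42643,0,0,0,0,0,46143,0.00
T6,8.02,97782,234,250,238,226,215,144030,11.59
T7,38.30,20670,1117,1118,1112,1101,1085,69806,11.15
T8,12.35,42643,360,357,352,346,339,89806,11.28
T9,49.35,97782,1439,1534,1461,1390,1320,140530,11.59
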