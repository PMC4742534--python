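# hypocotyl output-module parameters
# seed = 3, budget = 1200, shape cost = 0.1528
v_pif = 0.03916242875
K_ec_pif = 0.4313805088
dm_pif = 0.04718083373
pt_pif = 0.7571712451
dp_pif_l = 3.638001892
dp_pif_d = 0.3474959776
k_growth = 0.03180309096
K_growth = 1.035296494
g0 = 0.002759934877
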