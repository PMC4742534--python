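# reference clock parameter set (34 free parameters)
# produced by scripts/fit_clock.py: constraint-based fit against the
# extended cost spec (seeded differential evolution + Nelder-Mead,
# warm-started across rounds; final seed 19, budget 10000), followed by
# a uniform rescale of all rate parameters pinning the wild-type
# free-running period in continuous light to 24.0 h.
# free-parameter ledger: 4 v + 2 q + 10 K + 5 mRNA decay (CL split
# light/dark) + 5 translation (CL split) + 6 protein decay (P97/P51
# split) + 2 for protein P = 34.  Hill n = 2 and the EL dark fraction
# 0.25 are structural constants, not free parameters.
v_cl = 11.2994264
v_p97 = 0.3919474421
v_p51 = 1.052985756
v_el = 1.964617876
q_cl = 107.2530112
q_p97 = 8.382455194
K_p97_cl = 0.2480838691
K_p51_cl = 0.5039380624
K_cl_p97 = 0.6620064699
K_p51_p97 = 0.6917542488
K_ec_p97 = 0.7216543866
K_cl_p51 = 0.4738775956
K_p51_p51 = 1.159471671
K_cl_el = 0.7417772963
K_p51_el = 3.923218254
K_ec_el = 1.58211028
dm_cl_l = 0.4138414792
dm_cl_d = 0.1285314515
dm_p97 = 0.4825048292
dm_p51 = 0.7010692964
dm_el = 0.3324248373
pt_cl_l = 0.8290278823
pt_cl_d = 1.136495317
pt_p97 = 12.85180052
pt_p51 = 0.6880195381
pt_ec = 0.4067020911
dp_cl = 0.5794017779
dp_p97_l = 0.1235880756
dp_p97_d = 0.3911992919
dp_p51_l = 1.235837507
dp_p51_d = 0.2651822054
dp_ec = 0.5117623838
v_p = 0.2856791101
d_p = 1.041396646
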