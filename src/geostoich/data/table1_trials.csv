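experiment,feed,protein_intake,lipid_intake,protein_digestibility,lipid_digestibility,growth_rate,growth_sd
1,FM,0.02750,0.00833,0.796,0.612,0.0043,0.03
1,KM,0.02472,0.00829,0.863,0.672,0.0051,0.03
1,SBM,0.02806,0.00880,0.913,0.503,0.0057,0.03
1,SWM,0.03392,0.01515,0.949,0.665,0.006,0.09
2,D1,0.02766,0.00426,,0.86,0.0126,0.09
2,D2,0.02552,0.00428,,0.823,0.0109,0.06
2,D3,0.02418,0.00411,,0.814,0.011,0.09
2,D4,0.02537,0.00453,,0.769,0.0102,0.11
2,D5,0.02693,0.00498,,0.797,0.0123,0.07
2,D6,0.02615,0.00504,,0.805,0.011,0.07
3,BM0%,0.07381,0.02098,,,0.0233,0.10
3,BM1.6%,0.07473,0.02090,,,0.027,0.05
3,BM3.1%,0.07889,0.02283,,,0.0243,0.13
3,BM6.3%,0.07844,0.02179,,,0.023,0.06
3,BM12.5%,0.06118,0.01658,,,0.0235,0.04
3,BM25%,0.06965,0.01770,,,0.0252,0.04
3,BMHS,0.08270,0.01721,,,0.0326,0.07
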