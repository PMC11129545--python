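symbol,ka1_keV,ka2_keV,kb1_keV,k_edge_keV,omega_k
Mo,17.479,17.374,19.608,20.000,0.765
Cd,23.174,22.984,26.096,26.711,0.843
Te,27.472,27.202,30.995,31.814,0.875
La,33.442,33.034,37.801,38.925,0.906
Gd,42.996,42.309,48.697,50.239,0.932
W,59.318,57.982,67.244,69.525,0.958
Pt,66.832,65.112,75.748,78.395,0.963
Au,68.804,66.990,77.985,80.725,0.964
Pb,74.969,72.805,84.936,88.005,0.967
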