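symbol,line,energy_keV,rel_intensity,fluorescence_yield
Mo,Ka,17.444,0.835,0.765
Mo,Kb,19.608,0.165,0.765
Cd,Ka,23.111,0.83,0.843
Cd,Kb,26.096,0.17,0.843
Te,Ka,27.382,0.82,0.875
Te,Kb,30.995,0.18,0.875
La,Ka,33.306,0.8,0.906
La,Kb,37.801,0.2,0.906
Gd,Ka,42.767,0.79,0.932
Gd,Kb,48.697,0.21,0.932
W,Ka,58.873,0.78,0.958
W,Kb,67.244,0.22,0.958
Pt,Ka,66.259,0.775,0.963
Pt,Kb,75.748,0.225,0.963
Au,Ka,68.199,0.775,0.964
Au,Kb,77.985,0.225,0.964
Pb,Ka,74.248,0.77,0.967
Pb,Kb,84.936,0.23,0.967
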