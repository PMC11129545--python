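symbol,Z,atomic_mass,density_g_cm3,k_edge_keV,l3_edge_keV
H,1,1.008,8.375e-05,0.0136,0.0
Be,4,9.0122,1.848,0.1115,0.0
C,6,12.011,2.0,0.2842,0.0
O,8,15.999,0.001332,0.5431,0.0
F,9,18.998,0.00158,0.6971,0.0
Al,13,26.982,2.699,1.5596,0.0727
Mo,42,95.95,10.22,20.0,2.52
Cd,48,112.414,8.65,26.711,3.538
Te,52,127.6,6.24,31.814,4.341
La,57,138.905,6.15,38.925,5.483
Gd,64,157.25,7.9,50.239,7.243
W,74,183.84,19.3,69.525,10.207
Pt,78,195.084,21.45,78.395,11.564
Au,79,196.967,19.32,80.725,11.919
Pb,82,207.2,11.35,88.005,13.035
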