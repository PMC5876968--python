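injection_index,Dg_um,mass_flow_kg_s
1,0.392,2.53e-11
2,0.604,8.35e-11
3,0.866,1.48e-9
4,1.335,2.48e-8
5,1.910,1.61e-7
6,2.945,9.76e-7
7,4.535,2.49e-6
8,6.495,1.93e-6
9,10.000,5.52e-7
10,14.850,6.37e-8
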