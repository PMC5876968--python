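injection_index,Dg_um,mass_flow_kg_s
1,0.392,5.44e-9
2,0.604,4.27e-9
3,0.866,5.04e-8
4,1.335,3.84e-7
5,1.910,1.09e-6
6,2.945,1.91e-6
7,4.535,1.00e-6
8,6.495,2.46e-7
9,10.000,2.57e-7
10,14.850,7.81e-8
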