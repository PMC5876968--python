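injection_index,Dg_um,mass_flow_kg_s
1,0.375,1.43e-9
2,0.577,9.02e-10
3,0.828,1.18e-8
4,1.275,9.35e-8
5,1.825,2.87e-7
6,2.810,5.14e-7
7,4.330,1.79e-7
8,6.205,5.26e-8
9,9.555,1.21e-7
10,14.19,2.31e-8
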