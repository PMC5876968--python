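injection_index,Dg_um,mass_flow_kg_s
1,0.375,6.08e-12
2,0.577,1.49e-11
3,0.828,2.77e-10
4,1.275,4.82e-9
5,1.825,3.30e-8
6,2.810,1.91e-7
7,4.330,5.77e-7
8,6.205,4.64e-7
9,9.555,1.44e-7
10,14.19,1.72e-8
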