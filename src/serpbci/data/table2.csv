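patient_id,impaired_side,amplitude_d_ma,amplitude_v_ma,Ci,CPi,Pi,Cz,Cc,max_all,max_subset1,max_subset2
1,R,18,16,70,65,55,55,35,70,70,55
2,R,14,12,95,90,100,85,85,100,100,85
3,R,17,12,70,75,70,50,65,75,75,65
4,R,15,12,90,45,55,90,80,90,90,90
5,R,11,11,75,85,75,70,70,85,85,70
6,L,14,12,80,80,75,85,55,85,80,85
7,L,16,16,95,100,90,90,90,100,100,90
8,L,14,12,70,85,45,70,65,85,85,70
9,L,11,11,60,60,75,50,65,75,75,65
10,L,12,11,80,75,50,75,75,80,80,75
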