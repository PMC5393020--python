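case_id,sex,age,height,weight,lenke,pt_sup_end,mt_sup_end,mt_apex,mt_inf_end,pt_cobb,mt_cobb,tll_cobb,pt_bend_left,pt_bend_right,mt_bend_left,mt_bend_right,tll_bend_left,tll_bend_right,mt_avr,tll_avr,kyphosis,lordosis,uiv,liv
1,F,14,154,52,1A,T2,T6,T9,T12,32,55,37,22,35,59,29,2,49,16,5,7,42,T4,L2
2,F,16,162,56,1A,T2,T6,T11,L2,31,52,37,10,41,60,25,5,50,17,3,23,37,T4,L3
3,F,19,162,47,3B,T2,T5,T8,T11,39,58,39,12,42,63,29,20,42,18,7,37,27,T4,L1
4,F,17,168,56,4A,T2,T5,T8,T11,52,60,30,17,54,64,38,9,40,19,7,28,45,T3,L1
5,F,14,170,59,3B,T2,T5,T8,T12,31,64,42,24,35,65,50,5,65,19,3,22,33,T3,L1
6,M,15,172,55,3C,T2,T7,T10,L1,34,62,48,6,37,62,27,30,50,20,11,11,15,T4,L2
7,F,16,165,53,1A,T2,T5,T9,L1,28,44,35,20,32,73,10,10,42,19,6,20,47,T4,L2
8,F,15,170,48,1A,T2,T4,T8,T12,9,48,39,5,20,55,30,10,45,18,11,18,40,T4,L2
9,F,15,159,59,3C,T2,T6,T9,T12,40,67,40,15,41,63,35,9,70,22,9,7,30,T3,L2
10,F,14,148,39,2A,T2,T5,T9,T11,42,51,32,28,46,60,30,2,49,19,3,15,32,T3,L1
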