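identifier,reference,figure,case_label,phase,y0,y1,dt_years,lambda,printed_odds0,printed_odds1,printed_s_hat,mutation
1,Klimiankou2016,Figure 4E,CN pt. 21,unclassified,0.13,0.14,0.45,24,0.15,0.16,0.002,Q749
2,Klimiankou2016,Figure 4E,CN pt. 11,unclassified,0.03,0.10,1.15,24,0.03,0.12,0.047,Q754
3,Klimiankou2016,Figure 4E,CN pt. 27,unclassified,0.01,0.06,1.75,24,0.01,0.06,0.053,Q741
4,Klimiankou2016,Figure 4E,CN pt. 19,unclassified,0.13,0.15,2.90,24,0.15,0.18,0.002,Y752
5,Klimiankou2016,Figure 4E,CN pt. 13,unclassified,0.13,0.07,0.45,24,0.14,0.08,-0.059,Q741
6,Beekman2012,Figure S4,pt. ph. 1,MDS,0.06,0.11,6.00,24,0.07,0.12,0.004,D715
7,Beekman2012,Figure S4,pt. ph. 2,AML,0.11,0.49,9.00,24,0.12,0.97,0.010,D715
8,Skokowa2014,Figure S3,pt. 6 ph. 1,MDS,0.24,0.56,13.00,24,0.32,1.27,0.004,Q726X
9,Skokowa2014,Figure S3,pt. 6 ph. 2,AML,0.56,0.83,3.00,24,1.27,4.88,0.019,Q726X
10,Skokowa2014,Figure S3,pt. 10,MDS,0.01,0.02,3.00,24,0.01,0.02,0.007,Q726P
11,Skokowa2014,Figure S3,pt. 16 ph. 1,MDS,0.10,0.30,4.50,24,0.11,0.43,0.012,Q720X
12,Skokowa2014,Figure S3,pt. 16 ph. 2,AML,0.30,0.33,0.33,24,0.43,0.49,0.017,Q720X
13,Skokowa2014,Figure S3,pt. 19 ph. 1,MDS,0.28,0.43,2.25,24,0.39,0.75,0.012,Y729X
14,Skokowa2014,Figure S3,pt. 19 ph. 2,AML,0.43,0.65,0.75,24,0.75,1.86,0.050,Y729X
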