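sample_id,age,status,n_igg,n_emhc,n_total,ri_printed,pct_igg_printed,pct_emhc_printed
DMD 18,7,DMD,48,492,2747,10.3,1.75,17.91
DMD 29,7,DMD,29,205.5,1484,7.1,1.95,13.85
DMD 33a,8,DMD,19,131,1520,6.9,1.25,8.62
DMD 58a,8,DMD,26,189,1089,7.3,2.39,17.36
DMD 05b,8,DMD,13,87,874,6.7,1.49,9.95
DMD 09,9,DMD,21,105,774,5.0,2.71,13.57
DMD 36,9,DMD,40.5,87.5,689,2.2,5.88,12.70
DMD 28,10,DMD,38,135,2324,3.6,1.64,5.81
DMD 44,10,DMD,17,31,822.5,1.8,2.07,3.77
DMD 32,11,DMD,156,324,2195,2.1,7.11,14.76
CTRL 12,8,CTRL,0,0,6771,undefined,0.00,0.00
CTRL 77a,10,CTRL,10,3,5721,0.3,0.17,0.05
CTRL 76,11,CTRL,5,0,4737,0.0,0.11,0.00
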