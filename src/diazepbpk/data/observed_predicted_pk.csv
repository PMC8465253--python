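# Observed vs model-predicted PK parameters for the 20 compiled clinical
# profiles (6 IV, 5 oral, 6 intranasal, 3 rectal).  cmax in ng/mL,
# auc_0_t in ng.h/mL, cl in L/h (dose/AUC0-t; CL/F for extravascular
# routes).  Ratios are always recomputed from these columns, never
# shipped pre-rounded.
route,reference,dose_mg,parameter,observed,predicted
iv,B46,2,cmax,157.06,154.39
iv,B46,2,auc_0_t,285.45,256.60
iv,B46,2,cl,7.00,7.79
iv,B47,5,cmax,332.28,452.92
iv,B47,5,auc_0_t,455.11,522.20
iv,B47,5,cl,10.98,9.57
iv,B48,5,cmax,492.1,479.77
iv,B48,5,auc_0_t,851.74,1305.30
iv,B48,5,cl,5.87,3.83
iv,B49,7.5,cmax,536.44,605.14
iv,B49,7.5,auc_0_t,1244,1428.08
iv,B49,7.5,cl,6.27,5.46
iv,B15,10,cmax,623,586.11
iv,B15,10,auc_0_t,3505.37,3117.92
iv,B15,10,cl,2.85,3.2
iv,B50,10,cmax,642.95,634.13
iv,B50,10,auc_0_t,4491.90,4364.79
iv,B50,10,cl,2.22,2.29
oral,B51,2,cmax,62.07,63.97
oral,B51,2,auc_0_t,330,406.55
oral,B51,2,cl,6.06,4.91
oral,B51,5,cmax,125.24,159.95
oral,B51,5,auc_0_t,784.19,1012.40
oral,B51,5,cl,6.37,4.93
oral,B15,10,cmax,325,311.87
oral,B15,10,auc_0_t,3487,2965.75
oral,B15,10,cl,2.86,3.37
oral,B51,10,cmax,255.53,322.62
oral,B51,10,auc_0_t,1540.28,2026.76
oral,B51,10,cl,6.49,4.93
oral,B52,10,cmax,352,318.99
oral,B52,10,auc_0_t,1445.96,1493.59
oral,B52,10,cl,6.91,6.66
intranasal,B46,2,cmax,46.25,39.66
intranasal,B46,2,auc_0_t,161.73,159.94
intranasal,B46,2,cl,12.36,12.5
intranasal,B47,5,cmax,102.66,127.34
intranasal,B47,5,auc_0_t,309.82,352.62
intranasal,B47,5,cl,16.13,14.18
intranasal,B48,10,cmax,218.15,222.08
intranasal,B48,10,auc_0_t,1513.78,1532.92
intranasal,B48,10,cl,6.60,6.52
intranasal,B48,10,cmax,172.99,222.48
intranasal,B48,10,auc_0_t,1084,1523.59
intranasal,B48,10,cl,9.22,6.56
intranasal,B47,10,cmax,180.51,254.69
intranasal,B47,10,auc_0_t,588.64,710.80
intranasal,B47,10,cl,16.98,14.06
intranasal,B50,10,cmax,236.82,222.70
intranasal,B50,10,auc_0_t,3558.44,3033.84
intranasal,B50,10,cl,2.81,3.29
rectal,B15,10,cmax,297,224.17
rectal,B15,10,auc_0_t,3566.35,2699.95
rectal,B15,10,cl,2.80,3.70
rectal,B15,10,cmax,254,229.40
rectal,B15,10,auc_0_t,3258.12,2666.01
rectal,B15,10,cl,3.06,3.75
rectal,B49,15,cmax,384.86,350.74
rectal,B49,15,auc_0_t,2070.02,2028.11
rectal,B49,15,cl,7.24,7.39
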