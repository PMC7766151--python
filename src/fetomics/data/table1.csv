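patient_id,gender,age,initial_diagnosis,idh,mgmt,eor,weeks_since_rt,diagnosis,confirmation,pfs_months,os_months,pfs_censored,os_censored,tbr_mean,tbr_max,ttp_min,slope_suv_h
1,m,58,GBM,wt,unmeth,PR,6,EP,histomolecular,4,9,0,0,1.8,1.9,12.5,-0.4
2,m,61,GBM,wt,unmeth,CR,4,EP,histomolecular,5,5,0,1,2.1,2.4,37.5,0.4
3,m,52,GBM,wt,unmeth,PR,4,EP,histomolecular,5,15,0,0,2.2,2.8,37.5,1.1
4,m,69,GBM,wt,unmeth,PR,8,EP,histomolecular,6,12,0,0,1.9,1.9,22.5,0.3
5,f,43,GBM,wt,unmeth,CR,8,EP,follow-up,5,24,0,1,2.0,2.5,32.5,0.3
6,m,52,GBM,wt,unmeth,CR,7,EP,follow-up,5,16,0,0,1.9,2.3,32.5,0.6
7,m,72,GBM,wt,unmeth,B,5,EP,follow-up,4,7,0,0,2.2,3.7,18.5,-0.8
8,m,51,GBM,wt,meth,PR,6,EP,histomolecular,5,22,0,1,2.5,3.9,12.5,-1.9
9,m,44,GBM,wt,unmeth,CR,3,EP,follow-up,3,9,0,0,1.9,2.6,37.5,1.3
10,m,61,GBM,wt,unmeth,B,8,EP,follow-up,5,6,0,1,2.2,2.8,27.5,-0.2
11,m,57,GBM,wt,unmeth,B,5,EP,follow-up,2,2,0,1,2.1,2.8,18.5,-1.5
12,m,42,GBM,wt,meth,CR,12,EP,follow-up,5,34,0,0,2.1,2.5,15.5,0.1
13,m,79,GBM,wt,,CR,12,EP,histomolecular,,6,0,1,1.9,1.9,22.5,0.1
14,m,76,GBM,wt,meth,B,4,EP,follow-up,4,6,0,0,2.0,2.6,18.5,-0.2
15,f,52,GBM,wt,meth,PR,8,EP,follow-up,5,15,0,1,2.0,2.0,27.5,0.2
16,m,54,GBM,wt,unmeth,PR,8,EP,follow-up,8,10,0,0,1.8,1.8,32.5,0.9
17,m,69,GBM,wt,meth,B,1,EP,follow-up,4,4,0,0,1.9,2.1,27.5,0.9
18,f,52,GBM,wt,unmeth,PR,4,EP,follow-up,8,11,0,1,2.6,3.5,37.5,1.0
19,f,71,GBM,wt,meth,PR,3,PSP,histomolecular,12,21,0,0,1.8,1.8,37.5,0.4
20,f,76,GBM,wt,meth,CR,8,PSP,histomolecular,20,20,0,1,1.9,2.2,22.5,-0.3
21,f,58,GBM,wt,unmeth,PR,8,PSP,follow-up,24,38,0,0,2.0,2.1,22.5,-0.1
22,m,50,GBM,wt,unmeth,CR,4,PSP,follow-up,16,23,0,0,1.9,2.0,37.5,1.0
23,m,34,GBM,wt,meth,PR,8,PSP,follow-up,60,65,0,1,1.8,1.8,37.5,0.4
24,f,48,GBM,wt,,CR,8,PSP,histomolecular,,14,0,1,1.9,1.9,27.5,-0.5
25,f,64,GBM,wt,meth,CR,4,PSP,follow-up,,50,0,0,1.7,1.7,37.5,1.2
26,f,66,GBM,wt,unmeth,B,12,PSP,follow-up,10,12,0,0,2.3,3.0,22.5,-0.7
27,m,66,GBM,wt,meth,B,12,PSP,follow-up,16,23,0,1,2.2,2.5,27.5,0.4
28,f,49,GBM,wt,unmeth,PR,6,PSP,follow-up,10,11,0,1,1.9,2.2,27.5,0.0
29,f,24,AA,wt,unmeth,B,11,PSP,follow-up,8,12,0,1,2.1,2.4,18.5,-0.5
30,f,51,GBM,wt,unmeth,CR,8,PSP,follow-up,8,18,0,0,1.8,1.8,27.5,0.6
31,m,44,GBM,wt,unmeth,PR,10,PSP,follow-up,6,12,0,0,1.9,1.9,32.5,0.2
32,m,65,GBM,wt,meth,CR,6,PSP,follow-up,11,13,0,1,1.8,1.8,37.5,0.9
33,f,68,GBM,wt,unmeth,PR,9,PSP,follow-up,10,10,0,1,1.8,1.8,37.5,0.9
34,m,48,GBM,mut,meth,CR,6,PSP,follow-up,24,24,1,1,1.8,1.8,37.5,0.5
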