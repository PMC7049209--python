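# Prospective 34-patient SAH/MIA validation cohort; one row per aneurysm.
# location = five-region pooling of `site`; ruptured = bleeding source established by
# surgical inspection where available, otherwise by expert/bleeding-pattern validation.
# published_score is the score exactly as printed in the source table (reference only;
# rows 2-1, 5-7 and 6-2 are known misprints there). Patient covariates were not published.
patient_id,aneurysm_id,size_mm,location,shape,ruptured,age_years,smoker,hypertension,site,treatment,published_score
1,1-1,7,MCA,irregular,1,NA,NA,NA,MCA left,surgical,0.4321
1,1-2,3,ACOM_AA,regular,0,NA,NA,NA,AcomA,no treatment,0.1281
2,2-1,6,PCOM,regular,1,NA,NA,NA,PcomA,surgical,0.0216
2,2-2,2,POSTERIOR,regular,0,NA,NA,NA,Basilar tip,no treatment,-0.0977
3,3-1,7,MCA,regular,1,NA,NA,NA,MCA left,surgical,-0.1066
3,3-2,5,MCA,regular,0,NA,NA,NA,MCA right,no treatment,-0.192
4,4-1,6,PCOM,irregular,1,NA,NA,NA,PcomA,endovascular,0.7845
4,4-2,3,ACOM_AA,regular,0,NA,NA,NA,A3,no treatment,0.1281
5,5-1,7,ACOM_AA,irregular,1,NA,NA,NA,AcomA,endovascular,0.8376
5,5-2,7,PCOM,regular,0,NA,NA,NA,PcomA,combined,0.2885
5,5-3,6,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.1493
5,5-4,3,ACOM_AA,regular,0,NA,NA,NA,A1,endovascular,0.1281
5,5-5,4,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA,no treatment,-0.4265
5,5-6,2,POSTERIOR,regular,0,NA,NA,NA,P1,no treatment,-0.0977
5,5-7,3,POSTERIOR,regular,0,NA,NA,NA,Basilar tip,no treatment,-0.0556
6,6-1,10,POSTERIOR,regular,1,NA,NA,NA,Basilar tip,endovascular,0.2439
6,6-2,3,POSTERIOR,regular,0,NA,NA,NA,Basilar side,no treatment,-0.0557
7,7-1,6,PCOM,irregular,1,NA,NA,NA,PcomA,endovascular,0.7845
7,7-2,4,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.2347
8,8-1,5,ACOM_AA,regular,1,NA,NA,NA,AcomA,endovascular,0.2135
8,8-2,2,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.3201
9,9-1,5,ACOM_AA,irregular,1,NA,NA,NA,AcomA,surgical,0.7522
9,9-2,13,MCA,regular,0,NA,NA,NA,MCA,surgical,0.1496
10,10-1,3,ACOM_AA,regular,1,NA,NA,NA,AcomA,endovascular,0.1281
10,10-2,2,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.3201
11,11-1,17,MCA,regular,1,NA,NA,NA,MCA left,surgical,0.3204
11,11-2,7,MCA,regular,0,NA,NA,NA,MCA right,no treatment,-0.1066
12,12-1,6,POSTERIOR,irregular,1,NA,NA,NA,Basilar tip,endovascular,0.6118
12,12-2,3,PCOM,regular,0,NA,NA,NA,PcomA,endovascular (staged treatment),0.1177
13,13-1,3,ACOM_AA,regular,1,NA,NA,NA,AcomA,endovascular,0.1281
13,13-2,3,PCOM,regular,0,NA,NA,NA,PcomA,endovascular,0.1177
13,13-3,2,ICA_WO_PCOM,regular,0,NA,NA,NA,OphthalmicA,no treatment,-0.5119
13,13-4,2,POSTERIOR,regular,0,NA,NA,NA,VA,no treatment,-0.0977
14,14-1,4,ACOM_AA,regular,1,NA,NA,NA,A3,endovascular,0.1708
14,14-2,3,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.2774
14,14-3,1,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.3628
15,15-1,8,PCOM,regular,1,NA,NA,NA,PcomA right,surgical,0.3312
15,15-2,4,PCOM,regular,0,NA,NA,NA,PcomA left,no treatment,0.1604
16,16-1,10,MCA,regular,1,NA,NA,NA,MCA left,surgical,0.0215
16,16-2,2,MCA,regular,0,NA,NA,NA,MCA right,no treatment,-0.3201
17,17-1,5,POSTERIOR,regular,1,NA,NA,NA,PICA left,endovascular,0.0304
17,17-2,2,POSTERIOR,regular,0,NA,NA,NA,SCA left,no treatment,-0.0977
18,18-1,9,POSTERIOR,regular,1,NA,NA,NA,VB junction,endovascular,0.2012
18,18-2,4,ACOM_AA,regular,0,NA,NA,NA,AcomA,no treatment,0.1708
18,18-3,2,ACOM_AA,regular,0,NA,NA,NA,A2,no treatment,0.0854
19,19-1,4,MCA,regular,1,NA,NA,NA,MCA right,no treatment (aSDH right),-0.2347
19,19-2,2,MCA,regular,0,NA,NA,NA,MCA left,no treatment,-0.3201
20,20-1,8,MCA,irregular,1,NA,NA,NA,MCA,surgical,0.4748
20,20-2,4,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA,no treatment,-0.4265
20,20-3,3,ACOM_AA,regular,0,NA,NA,NA,A3,no treatment,0.1281
21,21-1,5,MCA,regular,1,NA,NA,NA,MCA left,surgical,-0.192
21,21-2,5,MCA,regular,0,NA,NA,NA,MCA right,no treatment,-0.192
22,22-1,9,MCA,irregular,1,NA,NA,NA,MCA left,surgical,0.5175
22,22-2,9,MCA,regular,0,NA,NA,NA,MCA right,surgical (2 stage treatment),-0.0212
23,23-1,9,ACOM_AA,irregular,1,NA,NA,NA,AcomA,endovascular,0.923
23,23-2,7,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA,no treatment,-0.2984
24,24-1,6,POSTERIOR,irregular,0,NA,NA,NA,Basilar tip,endovascular,0.6118
24,24-2,10,MCA,regular,1,NA,NA,NA,MCA right,surgical,0.0215
25,25-1,8,MCA,regular,1,NA,NA,NA,MCA right,surgical,-0.0639
25,25-2,4,MCA,regular,0,NA,NA,NA,MCA left,no treatment,-0.2347
25,25-3,4,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA left,no treatment,-0.4265
26,26-1,7,MCA,regular,1,NA,NA,NA,MCA right,surgical,-0.1066
26,26-2,2,MCA,regular,0,NA,NA,NA,M2 right,surgical,-0.3201
26,26-3,3,MCA,regular,0,NA,NA,NA,MCA left,no treatment,-0.2774
27,27-1,7,PCOM,regular,1,NA,NA,NA,PcomA left,endovascular,0.2885
27,27-2,7,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA right,endovascular,-0.2984
28,28-1,10,MCA,regular,1,NA,NA,NA,M2 right,surgical,0.0215
28,28-2,6,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA left,no treatment,-0.3411
28,28-3,3,MCA,regular,0,NA,NA,NA,M2 left,no treatment,-0.2774
29,29-1,9,ICA_WO_PCOM,regular,1,NA,NA,NA,ICA,endovascular,-0.213
29,29-2,3,MCA,regular,0,NA,NA,NA,MCA,no treatment,-0.2774
30,30-1,10,PCOM,regular,1,NA,NA,NA,PcomA,endovascular,0.4166
30,30-2,4,ACOM_AA,regular,0,NA,NA,NA,AcomA,no treatment,0.1708
31,31-1,11,ACOM_AA,regular,1,NA,NA,NA,AcomA,endovascular,0.4697
31,31-2,5,PCOM,regular,0,NA,NA,NA,PcomA,no treatment,0.2031
32,32-1,9,ACOM_AA,regular,1,NA,NA,NA,ACA (A3),endovascular,0.3843
32,32-2,3,MCA,regular,0,NA,NA,NA,MCA left,no treatment,-0.2774
32,32-3,2,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA left,no treatment,-0.5119
32,32-4,6,POSTERIOR,regular,0,NA,NA,NA,SCA right,no treatment,0.0731
33,33-1,5,ACOM_AA,regular,1,NA,NA,NA,AcomA,endovascular,0.2135
33,33-2,3,MCA,regular,0,NA,NA,NA,M3 right,surgical,-0.2774
34,34-1,9,PCOM,regular,1,NA,NA,NA,PcomA right,surgical,0.3739
34,34-2,6,ICA_WO_PCOM,regular,0,NA,NA,NA,ICA left,no treatment,-0.3411
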