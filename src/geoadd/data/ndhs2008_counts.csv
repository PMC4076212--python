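variable,level,n_overweight_obese,n_normal
educ_respondent,none,1808,9730
educ_respondent,primary,1369,4543
educ_respondent,secondary,2009,3881
educ_respondent,higher,650,624
educ_partner,none,1472,7624
educ_partner,primary,1210,4048
educ_partner,secondary,1874,4813
educ_partner,higher,1124,1640
residence,urban,2500,4365
residence,rural,3336,14413
religion,catholic,724,1577
religion,other_christian,2604,6045
religion,islam,2372,10662
religion,traditionalist,88,360
religion,other,14,22
wealth,poorest,718,5279
wealth,poorer,828,4920
wealth,middle,1195,3745
wealth,richer,1386,2943
wealth,richest,1709,1891
ethnicity,ekoi,67,334
ethnicity,fulani,202,1787
ethnicity,hausa,1120,5275
ethnicity,ibibio,153,263
ethnicity,igala,99,215
ethnicity,igbo,1091,1708
ethnicity,ijaw_izon,297,544
ethnicity,kanuri_beriberi,115,584
ethnicity,tiv,102,626
ethnicity,yoruba,879,1934
ethnicity,others,1684,5400
state,Akwa Ibom,169,316
state,Anambra,222,248
state,Bauchi/Gombe,213,1544
state,Edo,230,357
state,Benue,92,683
state,Borno,193,693
state,Cross River,133,417
state,Adamawa,136,709
state,Imo,183,208
state,Kaduna,196,688
state,Kano,227,963
state,Katsina,113,929
state,Kwara,118,372
state,Lagos,357,354
state,Niger,199,762
state,Ogun,98,355
state,Ondo/Ekiti,254,690
state,Oyo,135,370
state,Nassarawa/Plateau,276,1083
state,Rivers/Bayelsa,410,631
state,Sokoto/Zamfara,230,1323
state,Abia,158,251
state,Delta,123,335
state,Enugu/Ebonyi,253,741
state,Jigawa,123,760
state,Kebbi,207,563
state,Kogi,141,352
state,Osun,82,343
state,Taraba,238,674
state,Yobe,87,741
state,Abuja,240,323
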