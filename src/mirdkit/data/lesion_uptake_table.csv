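patient_id,group,timepoint,suv_max,suv_mean,tumor_size_cm,uptake_pattern,metastasis_site
1,NEN,PET_10,4.53,2.58,4.4,heterogeneous,False
1,NEN,PET_1h,4.55,2.37,4.4,heterogeneous,False
1,NEN,PET_2h,5.70,2.93,4.4,heterogeneous,False
2,NEN,PET_10,10.36,5.31,4.9,heterogeneous,False
2,NEN,PET_1h,17.70,8.74,4.9,heterogeneous,False
2,NEN,PET_2h,14.32,7.73,4.9,heterogeneous,False
3,NEN,PET_10,7.85,4.10,4.4,heterogeneous,False
3,NEN,PET_1h,8.77,4.48,4.4,heterogeneous,False
3,NEN,PET_2h,15.35,7.86,4.4,heterogeneous,False
4,BC,PET_10,6.18,3.26,6.0,heterogeneous,False
4,BC,PET_1h,8.75,4.52,6.0,heterogeneous,False
4,BC,PET_2h,10.53,5.44,6.0,heterogeneous,False
5,NEN,PET_10,7.39,2.93,16.0,heterogeneous,True
5,NEN,PET_1h,9.39,3.20,16.0,heterogeneous,True
5,NEN,PET_2h,8.83,3.15,16.0,heterogeneous,True
6,BC,PET_10,4.88,4.59,1.1,homogeneous,False
6,BC,PET_1h,7.15,6.75,1.1,homogeneous,False
6,BC,PET_2h,8.02,6.79,1.1,homogeneous,False
7,BC,PET_10,3.05,1.67,1.4,homogeneous,False
7,BC,PET_1h,2.29,1.30,1.4,homogeneous,False
7,BC,PET_2h,2.66,1.94,1.4,homogeneous,False
8,BC,PET_10,7.09,4.18,1.8,homogeneous,False
8,BC,PET_1h,8.40,4.70,1.8,homogeneous,False
8,BC,PET_2h,7.10,4.04,1.8,homogeneous,False
9,BC,PET_10,4.24,2.36,0.9,homogeneous,False
9,BC,PET_1h,4.99,2.54,0.9,homogeneous,False
9,BC,PET_2h,4.45,2.58,0.9,homogeneous,False
10,NEN,PET_10,5.90,3.27,10.0,heterogeneous,False
10,NEN,PET_1h,7.58,3.69,10.0,heterogeneous,False
10,NEN,PET_2h,5.80,3.05,10.0,heterogeneous,False
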