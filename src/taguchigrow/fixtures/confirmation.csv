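species,parameter,sn_db,expected,predicted,error_pct
basil,no_leaf,28.30,21.04,20.78,1.25
basil,leaf_area,40.85,90.99,89.11,2.07
basil,fresh_leaf,21.09,9.15,9.04,1.17
basil,dry_leaf,17.65,0.11,0.10,2.68
basil,fresh_root,9.78,2.53,2.45,3.0
basil,dry_root,18.63,0.10,0.09,3.18
basil,chlorophyll,15.96,5.13,4.98,2.84
basil,N,9.31,2.81,2.74,2.5
basil,Fe,50.10,269.85,266.07,1.4
basil,Zn,32.28,39.28,38.60,1.75
basil,Cu,21.34,11.24,10.95,2.55
basil,Mn,35.87,58.84,57.10,2.96
basil,P,7.97,0.38,0.37,3.23
basil,K,8.63,2.56,2.64,1.07
basil,Ca,13.12,5.63,3.59,0.98
basil,Mg,1.26,0.82,0.81,0.88
basil,B,32.98,40.98,40.52,1.11
lettuce,no_leaf,31.24,34.10,33.33,2.26
lettuce,leaf_area,67.01,2117.41,2059.39,2.74
lettuce,fresh_leaf,34.84,51.08,50.45,1.24
lettuce,dry_leaf,4.29,1.51,1.50,0.82
lettuce,fresh_root,15.54,5.34,5.28,1.08
lettuce,dry_root,0.39,0.86,0.84,2.35
lettuce,chlorophyll,13.74,4.24,4.17,1.86
lettuce,N,14.77,4.36,4.27,2.03
lettuce,Fe,47.21,182.91,177.43,3.0
lettuce,Zn,32.51,33.36,32.97,1.17
lettuce,Cu,23.44,11.72,11.60,1.02
lettuce,Mn,41.60,93.97,93.06,0.97
lettuce,P,4.56,0.47,0.46,1.82
lettuce,K,15.93,4.94,4.88,1.10
lettuce,Ca,8.02,2.0,1.95,2.52
lettuce,Mg,1.95,1.0,0.98,2.11
lettuce,B,37.36,57.97,57.07,1.37
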