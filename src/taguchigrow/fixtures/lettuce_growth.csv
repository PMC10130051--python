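species,run,parameter,value
lettuce,1,no_leaf,11
lettuce,1,leaf_area,688
lettuce,1,fresh_leaf,17.15
lettuce,1,dry_leaf,0.48
lettuce,1,fresh_root,1.82
lettuce,1,dry_root,0.321
lettuce,1,chlorophyll,1.32
lettuce,2,no_leaf,14
lettuce,2,leaf_area,872
lettuce,2,fresh_leaf,21.72
lettuce,2,dry_leaf,0.67
lettuce,2,fresh_root,2.14
lettuce,2,dry_root,0.367
lettuce,2,chlorophyll,1.68
lettuce,3,no_leaf,17
lettuce,3,leaf_area,1071
lettuce,3,fresh_leaf,26.35
lettuce,3,dry_leaf,0.77
lettuce,3,fresh_root,1.77
lettuce,3,dry_root,0.311
lettuce,3,chlorophyll,1.38
lettuce,4,no_leaf,16
lettuce,4,leaf_area,1001
lettuce,4,fresh_leaf,24.85
lettuce,4,dry_leaf,0.72
lettuce,4,fresh_root,2.46
lettuce,4,dry_root,0.42
lettuce,4,chlorophyll,1.95
lettuce,5,no_leaf,18
lettuce,5,leaf_area,1120
lettuce,5,fresh_leaf,27.77
lettuce,5,dry_leaf,0.81
lettuce,5,fresh_root,3.1
lettuce,5,dry_root,0.455
lettuce,5,chlorophyll,2.26
lettuce,6,no_leaf,19
lettuce,6,leaf_area,1188
lettuce,6,fresh_leaf,29.45
lettuce,6,dry_leaf,0.86
lettuce,6,fresh_root,2.67
lettuce,6,dry_root,0.421
lettuce,6,chlorophyll,2.0
lettuce,7,no_leaf,18
lettuce,7,leaf_area,1127
lettuce,7,fresh_leaf,28.1
lettuce,7,dry_leaf,0.82
lettuce,7,fresh_root,2.82
lettuce,7,dry_root,0.472
lettuce,7,chlorophyll,2.22
lettuce,8,no_leaf,17
lettuce,8,leaf_area,1063
lettuce,8,fresh_leaf,26.35
lettuce,8,dry_leaf,0.77
lettuce,8,fresh_root,2.88
lettuce,8,dry_root,0.431
lettuce,8,chlorophyll,2.04
lettuce,9,no_leaf,19
lettuce,9,leaf_area,1188
lettuce,9,fresh_leaf,29.45
lettuce,9,dry_leaf,0.86
lettuce,9,fresh_root,2.62
lettuce,9,dry_root,0.432
lettuce,9,chlorophyll,2.11
lettuce,10,no_leaf,22
lettuce,10,leaf_area,1377
lettuce,10,fresh_leaf,34.1
lettuce,10,dry_leaf,1.01
lettuce,10,fresh_root,4.32
lettuce,10,dry_root,0.682
lettuce,10,chlorophyll,3.37
lettuce,11,no_leaf,20
lettuce,11,leaf_area,1245
lettuce,11,fresh_leaf,30.91
lettuce,11,dry_leaf,0.9
lettuce,11,fresh_root,2.51
lettuce,11,dry_root,0.405
lettuce,11,chlorophyll,2.1
lettuce,12,no_leaf,17
lettuce,12,leaf_area,998
lettuce,12,fresh_leaf,26.35
lettuce,12,dry_leaf,0.77
lettuce,12,fresh_root,2.72
lettuce,12,dry_root,0.421
lettuce,12,chlorophyll,2.12
lettuce,13,no_leaf,16
lettuce,13,leaf_area,992
lettuce,13,fresh_leaf,24.62
lettuce,13,dry_leaf,0.75
lettuce,13,fresh_root,2.58
lettuce,13,dry_root,0.385
lettuce,13,chlorophyll,1.97
lettuce,14,no_leaf,18
lettuce,14,leaf_area,1122
lettuce,14,fresh_leaf,27.9
lettuce,14,dry_leaf,0.82
lettuce,14,fresh_root,2.54
lettuce,14,dry_root,0.325
lettuce,14,chlorophyll,1.68
lettuce,15,no_leaf,14
lettuce,15,leaf_area,870
lettuce,15,fresh_leaf,22.0
lettuce,15,dry_leaf,0.63
lettuce,15,fresh_root,2.24
lettuce,15,dry_root,0.35
lettuce,15,chlorophyll,1.71
lettuce,16,no_leaf,19
lettuce,16,leaf_area,1172
lettuce,16,fresh_leaf,29.5
lettuce,16,dry_leaf,0.86
lettuce,16,fresh_root,3.15
lettuce,16,dry_root,0.476
lettuce,16,chlorophyll,2.32
lettuce,17,no_leaf,17
lettuce,17,leaf_area,1063
lettuce,17,fresh_leaf,26.37
lettuce,17,dry_leaf,0.78
lettuce,17,fresh_root,2.44
lettuce,17,dry_root,0.362
lettuce,17,chlorophyll,1.75
lettuce,18,no_leaf,13
lettuce,18,leaf_area,820
lettuce,18,fresh_leaf,20.15
lettuce,18,dry_leaf,0.59
lettuce,18,fresh_root,2.18
lettuce,18,dry_root,0.336
lettuce,18,chlorophyll,1.61
lettuce,19,no_leaf,15
lettuce,19,leaf_area,941
lettuce,19,fresh_leaf,23.51
lettuce,19,dry_leaf,0.69
lettuce,19,fresh_root,1.92
lettuce,19,dry_root,0.275
lettuce,19,chlorophyll,1.33
lettuce,20,no_leaf,11
lettuce,20,leaf_area,688
lettuce,20,fresh_leaf,17.05
lettuce,20,dry_leaf,0.5
lettuce,20,fresh_root,1.86
lettuce,20,dry_root,0.278
lettuce,20,chlorophyll,1.32
lettuce,21,no_leaf,14
lettuce,21,leaf_area,875
lettuce,21,fresh_leaf,21.67
lettuce,21,dry_leaf,0.63
lettuce,21,fresh_root,2.34
lettuce,21,dry_root,0.352
lettuce,21,chlorophyll,1.7
lettuce,22,no_leaf,11
lettuce,22,leaf_area,685
lettuce,22,fresh_leaf,17.2
lettuce,22,dry_leaf,0.49
lettuce,22,fresh_root,1.96
lettuce,22,dry_root,0.302
lettuce,22,chlorophyll,1.33
lettuce,23,no_leaf,10
lettuce,23,leaf_area,625
lettuce,23,fresh_leaf,15.42
lettuce,23,dry_leaf,0.45
lettuce,23,fresh_root,1.67
lettuce,23,dry_root,0.255
lettuce,23,chlorophyll,1.2
lettuce,24,no_leaf,12
lettuce,24,leaf_area,751
lettuce,24,fresh_leaf,18.6
lettuce,24,dry_leaf,0.55
lettuce,24,fresh_root,2.0
lettuce,24,dry_root,0.32
lettuce,24,chlorophyll,1.46
lettuce,25,no_leaf,35
lettuce,25,leaf_area,2172
lettuce,25,fresh_leaf,52.5
lettuce,25,dry_leaf,1.57
lettuce,25,fresh_root,5.31
lettuce,25,dry_root,0.882
lettuce,25,chlorophyll,4.25
lettuce,26,no_leaf,24
lettuce,26,leaf_area,1482
lettuce,26,fresh_leaf,37.2
lettuce,26,dry_leaf,1.08
lettuce,26,fresh_root,4.12
lettuce,26,dry_root,0.62
lettuce,26,chlorophyll,2.88
lettuce,27,no_leaf,28
lettuce,27,leaf_area,1750
lettuce,27,fresh_leaf,43.4
lettuce,27,dry_leaf,1.26
lettuce,27,fresh_root,4.62
lettuce,27,dry_root,0.7
lettuce,27,chlorophyll,3.26
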