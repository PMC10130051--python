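species,run,parameter,value
basil,1,no_leaf,4
basil,1,leaf_area,20
basil,1,fresh_leaf,1.82
basil,1,dry_leaf,0.02
basil,1,fresh_root,0.44
basil,1,dry_root,0.018
basil,1,chlorophyll,0.94
basil,2,no_leaf,7
basil,2,leaf_area,32
basil,2,fresh_leaf,3.22
basil,2,dry_leaf,0.035
basil,2,fresh_root,0.77
basil,2,dry_root,0.0315
basil,2,chlorophyll,1.64
basil,3,no_leaf,8
basil,3,leaf_area,34
basil,3,fresh_leaf,3.16
basil,3,dry_leaf,0.04
basil,3,fresh_root,0.88
basil,3,dry_root,0.036
basil,3,chlorophyll,1.89
basil,4,no_leaf,5
basil,4,leaf_area,21
basil,4,fresh_leaf,2.47
basil,4,dry_leaf,0.025
basil,4,fresh_root,0.65
basil,4,dry_root,0.0225
basil,4,chlorophyll,1.18
basil,5,no_leaf,11
basil,5,leaf_area,45
basil,5,fresh_leaf,5.21
basil,5,dry_leaf,0.055
basil,5,fresh_root,1.21
basil,5,dry_root,0.0495
basil,5,chlorophyll,2.63
basil,6,no_leaf,11
basil,6,leaf_area,48
basil,6,fresh_leaf,4.62
basil,6,dry_leaf,0.055
basil,6,fresh_root,1.34
basil,6,dry_root,0.0495
basil,6,chlorophyll,2.55
basil,7,no_leaf,17
basil,7,leaf_area,72
basil,7,fresh_leaf,7.82
basil,7,dry_leaf,0.085
basil,7,fresh_root,1.87
basil,7,dry_root,0.0765
basil,7,chlorophyll,3.91
basil,8,no_leaf,18
basil,8,leaf_area,76
basil,8,fresh_leaf,8.1
basil,8,dry_leaf,0.09
basil,8,fresh_root,2.11
basil,8,dry_root,0.081
basil,8,chlorophyll,4.28
basil,9,no_leaf,18
basil,9,leaf_area,78
basil,9,fresh_leaf,7.52
basil,9,dry_leaf,0.09
basil,9,fresh_root,2.08
basil,9,dry_root,0.081
basil,9,chlorophyll,4.32
basil,10,no_leaf,12
basil,10,leaf_area,51
basil,10,fresh_leaf,5.62
basil,10,dry_leaf,0.06
basil,10,fresh_root,1.32
basil,10,dry_root,0.054
basil,10,chlorophyll,2.85
basil,11,no_leaf,9
basil,11,leaf_area,37
basil,11,fresh_leaf,4.15
basil,11,dry_leaf,0.045
basil,11,fresh_root,1.13
basil,11,dry_root,0.0405
basil,11,chlorophyll,2.12
basil,12,no_leaf,12
basil,12,leaf_area,49
basil,12,fresh_leaf,5.44
basil,12,dry_leaf,0.06
basil,12,fresh_root,1.32
basil,12,dry_root,0.054
basil,12,chlorophyll,3.12
basil,13,no_leaf,15
basil,13,leaf_area,62
basil,13,fresh_leaf,6.78
basil,13,dry_leaf,0.075
basil,13,fresh_root,1.67
basil,13,dry_root,0.0675
basil,13,chlorophyll,3.27
basil,14,no_leaf,14
basil,14,leaf_area,57
basil,14,fresh_leaf,6.45
basil,14,dry_leaf,0.07
basil,14,fresh_root,1.44
basil,14,dry_root,0.063
basil,14,chlorophyll,3.34
basil,15,no_leaf,15
basil,15,leaf_area,63
basil,15,fresh_leaf,6.92
basil,15,dry_leaf,0.075
basil,15,fresh_root,1.57
basil,15,dry_root,0.0675
basil,15,chlorophyll,3.61
basil,16,no_leaf,9
basil,16,leaf_area,38
basil,16,fresh_leaf,4.5
basil,16,dry_leaf,0.045
basil,16,fresh_root,1.27
basil,16,dry_root,0.0405
basil,16,chlorophyll,2.17
basil,17,no_leaf,7
basil,17,leaf_area,31
basil,17,fresh_leaf,3.11
basil,17,dry_leaf,0.035
basil,17,fresh_root,0.82
basil,17,dry_root,0.0315
basil,17,chlorophyll,1.67
basil,18,no_leaf,12
basil,18,leaf_area,53
basil,18,fresh_leaf,5.35
basil,18,dry_leaf,0.06
basil,18,fresh_root,1.62
basil,18,dry_root,0.054
basil,18,chlorophyll,2.77
basil,19,no_leaf,13
basil,19,leaf_area,55
basil,19,fresh_leaf,5.62
basil,19,dry_leaf,0.067
basil,19,fresh_root,1.72
basil,19,dry_root,0.0585
basil,19,chlorophyll,3.12
basil,20,no_leaf,11
basil,20,leaf_area,47
basil,20,fresh_leaf,4.68
basil,20,dry_leaf,0.057
basil,20,fresh_root,1.08
basil,20,dry_root,0.0495
basil,20,chlorophyll,2.56
basil,21,no_leaf,16
basil,21,leaf_area,67
basil,21,fresh_leaf,7.21
basil,21,dry_leaf,0.08
basil,21,fresh_root,1.92
basil,21,dry_root,0.072
basil,21,chlorophyll,3.77
basil,22,no_leaf,11
basil,22,leaf_area,48
basil,22,fresh_leaf,5.21
basil,22,dry_leaf,0.055
basil,22,fresh_root,1.44
basil,22,dry_root,0.0495
basil,22,chlorophyll,2.47
basil,23,no_leaf,9
basil,23,leaf_area,39
basil,23,fresh_leaf,4.05
basil,23,dry_leaf,0.044
basil,23,fresh_root,1.34
basil,23,dry_root,0.0405
basil,23,chlorophyll,2.32
basil,24,no_leaf,12
basil,24,leaf_area,52
basil,24,fresh_leaf,5.32
basil,24,dry_leaf,0.06
basil,24,fresh_root,1.56
basil,24,dry_root,0.054
basil,24,chlorophyll,2.91
basil,25,no_leaf,13
basil,25,leaf_area,55
basil,25,fresh_leaf,5.8
basil,25,dry_leaf,0.064
basil,25,fresh_root,1.7
basil,25,dry_root,0.0585
basil,25,chlorophyll,3.12
basil,26,no_leaf,13
basil,26,leaf_area,56
basil,26,fresh_leaf,6.1
basil,26,dry_leaf,0.065
basil,26,fresh_root,1.87
basil,26,dry_root,0.0585
basil,26,chlorophyll,2.97
basil,27,no_leaf,14
basil,27,leaf_area,61
basil,27,fresh_leaf,6.23
basil,27,dry_leaf,0.07
basil,27,fresh_root,1.54
basil,27,dry_root,0.063
basil,27,chlorophyll,3.34
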