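species,run,parameter,value
lettuce,1,Fe,47.8
lettuce,1,Zn,10.2
lettuce,1,Cu,3.59
lettuce,1,Mn,25.07
lettuce,1,N,1.21
lettuce,1,P,0.13
lettuce,1,K,1.51
lettuce,1,Ca,0.6
lettuce,1,Mg,0.3
lettuce,1,B,15.37
lettuce,2,Fe,63.13
lettuce,2,Zn,12.78
lettuce,2,Cu,4.5
lettuce,2,Mn,33.11
lettuce,2,N,1.6
lettuce,2,P,0.17
lettuce,2,K,1.89
lettuce,2,Ca,0.76
lettuce,2,Mg,0.38
lettuce,2,B,20.31
lettuce,3,Fe,47.34
lettuce,3,Zn,10.84
lettuce,3,Cu,3.81
lettuce,3,Mn,24.83
lettuce,3,N,1.2
lettuce,3,P,0.13
lettuce,3,K,1.61
lettuce,3,Ca,0.84
lettuce,3,Mg,0.32
lettuce,3,B,15.23
lettuce,4,Fe,64.33
lettuce,4,Zn,12.01
lettuce,4,Cu,4.23
lettuce,4,Mn,33.74
lettuce,4,N,1.63
lettuce,4,P,0.18
lettuce,4,K,1.78
lettuce,4,Ca,0.71
lettuce,4,Mg,0.36
lettuce,4,B,20.69
lettuce,5,Fe,73.95
lettuce,5,Zn,13.8
lettuce,5,Cu,4.86
lettuce,5,Mn,38.78
lettuce,5,N,1.87
lettuce,5,P,0.2
lettuce,5,K,2.04
lettuce,5,Ca,0.82
lettuce,5,Mg,0.41
lettuce,5,B,23.79
lettuce,6,Fe,65.83
lettuce,6,Zn,12.29
lettuce,6,Cu,4.32
lettuce,6,Mn,34.53
lettuce,6,N,1.67
lettuce,6,P,0.18
lettuce,6,K,1.82
lettuce,6,Ca,0.93
lettuce,6,Mg,0.36
lettuce,6,B,21.18
lettuce,7,Fe,119.5
lettuce,7,Zn,27.11
lettuce,7,Cu,9.54
lettuce,7,Mn,62.67
lettuce,7,N,3.53
lettuce,7,P,0.38
lettuce,7,K,4.02
lettuce,7,Ca,1.32
lettuce,7,Mg,0.8
lettuce,7,B,38.44
lettuce,8,Fe,127.45
lettuce,8,Zn,25.72
lettuce,8,Cu,9.05
lettuce,8,Mn,66.85
lettuce,8,N,3.23
lettuce,8,P,0.35
lettuce,8,K,3.81
lettuce,8,Ca,1.52
lettuce,8,Mg,0.76
lettuce,8,B,41.0
lettuce,9,Fe,117.2
lettuce,9,Zn,24.92
lettuce,9,Cu,8.77
lettuce,9,Mn,61.47
lettuce,9,N,2.77
lettuce,9,P,0.3
lettuce,9,K,3.69
lettuce,9,Ca,1.58
lettuce,9,Mg,0.74
lettuce,9,B,37.7
lettuce,10,Fe,55.7
lettuce,10,Zn,20.2
lettuce,10,Cu,7.11
lettuce,10,Mn,29.21
lettuce,10,N,3.02
lettuce,10,P,0.33
lettuce,10,K,2.99
lettuce,10,Ca,1.2
lettuce,10,Mg,0.6
lettuce,10,B,17.92
lettuce,11,Fe,37.6
lettuce,11,Zn,13.35
lettuce,11,Cu,4.7
lettuce,11,Mn,19.72
lettuce,11,N,1.81
lettuce,11,P,0.2
lettuce,11,K,1.98
lettuce,11,Ca,0.89
lettuce,11,Mg,0.4
lettuce,11,B,12.1
lettuce,12,Fe,42.29
lettuce,12,Zn,13.49
lettuce,12,Cu,4.75
lettuce,12,Mn,22.18
lettuce,12,N,1.83
lettuce,12,P,0.2
lettuce,12,K,2.0
lettuce,12,Ca,0.8
lettuce,12,Mg,0.4
lettuce,12,B,13.6
lettuce,13,Fe,143.09
lettuce,13,Zn,26.71
lettuce,13,Cu,9.4
lettuce,13,Mn,75.05
lettuce,13,N,3.62
lettuce,13,P,0.39
lettuce,13,K,3.96
lettuce,13,Ca,1.38
lettuce,13,Mg,0.79
lettuce,13,B,46.03
lettuce,14,Fe,74.85
lettuce,14,Zn,13.97
lettuce,14,Cu,4.92
lettuce,14,Mn,39.26
lettuce,14,N,1.9
lettuce,14,P,0.2
lettuce,14,K,2.07
lettuce,14,Ca,1.28
lettuce,14,Mg,0.41
lettuce,14,B,24.08
lettuce,15,Fe,78.16
lettuce,15,Zn,14.59
lettuce,15,Cu,5.13
lettuce,15,Mn,40.99
lettuce,15,N,1.98
lettuce,15,P,0.21
lettuce,15,K,2.16
lettuce,15,Ca,0.86
lettuce,15,Mg,0.43
lettuce,15,B,25.14
lettuce,16,Fe,81.76
lettuce,16,Zn,15.26
lettuce,16,Cu,5.37
lettuce,16,Mn,42.88
lettuce,16,N,2.07
lettuce,16,P,0.22
lettuce,16,K,2.26
lettuce,16,Ca,1.1
lettuce,16,Mg,0.45
lettuce,16,B,26.3
lettuce,17,Fe,61.62
lettuce,17,Zn,11.5
lettuce,17,Cu,4.05
lettuce,17,Mn,32.32
lettuce,17,N,1.56
lettuce,17,P,0.17
lettuce,17,K,1.7
lettuce,17,Ca,1.68
lettuce,17,Mg,0.34
lettuce,17,B,19.82
lettuce,18,Fe,55.91
lettuce,18,Zn,10.44
lettuce,18,Cu,3.67
lettuce,18,Mn,29.32
lettuce,18,N,1.42
lettuce,18,P,0.15
lettuce,18,K,1.55
lettuce,18,Ca,0.62
lettuce,18,Mg,0.31
lettuce,18,B,17.99
lettuce,19,Fe,79.21
lettuce,19,Zn,14.79
lettuce,19,Cu,5.2
lettuce,19,Mn,41.54
lettuce,19,N,2.01
lettuce,19,P,0.22
lettuce,19,K,2.19
lettuce,19,Ca,1.88
lettuce,19,Mg,0.44
lettuce,19,B,25.48
lettuce,20,Fe,78.46
lettuce,20,Zn,14.65
lettuce,20,Cu,5.15
lettuce,20,Mn,41.15
lettuce,20,N,1.99
lettuce,20,P,0.21
lettuce,20,K,2.17
lettuce,20,Ca,0.87
lettuce,20,Mg,0.43
lettuce,20,B,25.24
lettuce,21,Fe,88.98
lettuce,21,Zn,16.61
lettuce,21,Cu,5.84
lettuce,21,Mn,46.67
lettuce,21,N,2.25
lettuce,21,P,0.24
lettuce,21,K,2.46
lettuce,21,Ca,0.98
lettuce,21,Mg,0.49
lettuce,21,B,28.62
lettuce,22,Fe,83.5
lettuce,22,Zn,6.12
lettuce,22,Cu,2.15
lettuce,22,Mn,43.79
lettuce,22,N,0.83
lettuce,22,P,0.09
lettuce,22,K,0.91
lettuce,22,Ca,0.36
lettuce,22,Mg,0.18
lettuce,22,B,26.86
lettuce,23,Fe,57.24
lettuce,23,Zn,7.07
lettuce,23,Cu,2.49
lettuce,23,Mn,30.02
lettuce,23,N,0.96
lettuce,23,P,0.1
lettuce,23,K,1.05
lettuce,23,Ca,0.42
lettuce,23,Mg,0.21
lettuce,23,B,18.41
lettuce,24,Fe,75.5
lettuce,24,Zn,6.62
lettuce,24,Cu,2.33
lettuce,24,Mn,39.6
lettuce,24,N,0.9
lettuce,24,P,0.1
lettuce,24,K,0.98
lettuce,24,Ca,0.39
lettuce,24,Mg,0.2
lettuce,24,B,24.29
lettuce,25,Fe,143.7
lettuce,25,Zn,24.69
lettuce,25,Cu,8.69
lettuce,25,Mn,75.37
lettuce,25,N,3.35
lettuce,25,P,0.36
lettuce,25,K,3.66
lettuce,25,Ca,1.64
lettuce,25,Mg,0.73
lettuce,25,B,46.23
lettuce,26,Fe,121.3
lettuce,26,Zn,18.85
lettuce,26,Cu,6.63
lettuce,26,Mn,63.62
lettuce,26,N,2.56
lettuce,26,P,0.28
lettuce,26,K,2.79
lettuce,26,Ca,1.12
lettuce,26,Mg,0.56
lettuce,26,B,39.02
lettuce,27,Fe,117.84
lettuce,27,Zn,22.0
lettuce,27,Cu,7.74
lettuce,27,Mn,61.8
lettuce,27,N,2.99
lettuce,27,P,0.32
lettuce,27,K,3.26
lettuce,27,Ca,1.3
lettuce,27,Mg,0.65
lettuce,27,B,37.91
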