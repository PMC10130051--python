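species,run,parameter,value
basil,1,Fe,66.5
basil,1,Zn,18.3
basil,1,Cu,5.19
basil,1,Mn,27.87
basil,1,N,1.3
basil,1,P,0.15
basil,1,K,1.2
basil,1,Ca,0.68
basil,1,Mg,0.39
basil,1,B,19.76
basil,2,Fe,62.81
basil,2,Zn,17.59
basil,2,Cu,4.99
basil,2,Mn,31.67
basil,2,N,1.25
basil,2,P,0.17
basil,2,K,1.16
basil,2,Ca,1.18
basil,2,Mg,0.37
basil,2,B,22.4
basil,3,Fe,96.06
basil,3,Zn,20.27
basil,3,Cu,5.75
basil,3,Mn,27.02
basil,3,N,1.44
basil,3,P,0.17
basil,3,K,1.33
basil,3,Ca,1.36
basil,3,Mg,0.43
basil,3,B,19.0
basil,4,Fe,90.52
basil,4,Zn,15.76
basil,4,Cu,4.47
basil,4,Mn,23.43
basil,4,N,1.12
basil,4,P,0.15
basil,4,K,1.04
basil,4,Ca,0.85
basil,4,Mg,0.33
basil,4,B,16.54
basil,5,Fe,140.58
basil,5,Zn,25.61
basil,5,Cu,7.27
basil,5,Mn,43.07
basil,5,N,1.82
basil,5,P,0.25
basil,5,K,1.69
basil,5,Ca,1.9
basil,5,Mg,0.54
basil,5,B,30.27
basil,6,Fe,136.3
basil,6,Zn,20.77
basil,6,Cu,5.89
basil,6,Mn,30.4
basil,6,N,1.48
basil,6,P,0.2
basil,6,K,1.37
basil,6,Ca,1.84
basil,6,Mg,0.44
basil,6,B,21.5
basil,7,Fe,209.0
basil,7,Zn,31.85
basil,7,Cu,9.04
basil,7,Mn,42.46
basil,7,N,2.26
basil,7,P,0.3
basil,7,K,2.1
basil,7,Ca,2.82
basil,7,Mg,0.67
basil,7,B,30.1
basil,8,Fe,242.0
basil,8,Zn,38.7
basil,8,Cu,10.98
basil,8,Mn,57.0
basil,8,N,2.75
basil,8,P,0.37
basil,8,K,2.55
basil,8,Ca,3.09
basil,8,Mg,0.81
basil,8,B,40.12
basil,9,Fe,230.92
basil,9,Zn,35.19
basil,9,Cu,9.99
basil,9,Mn,51.93
basil,9,N,2.5
basil,9,P,0.34
basil,9,K,2.31
basil,9,Ca,3.11
basil,9,Mg,0.74
basil,9,B,36.54
basil,10,Fe,121.92
basil,10,Zn,22.8
basil,10,Cu,6.47
basil,10,Mn,35.47
basil,10,N,1.62
basil,10,P,0.22
basil,10,K,1.5
basil,10,Ca,2.05
basil,10,Mg,0.48
basil,10,B,24.87
basil,11,Fe,113.32
basil,11,Zn,17.27
basil,11,Cu,4.9
basil,11,Mn,23.02
basil,11,N,1.23
basil,11,P,0.17
basil,11,K,1.14
basil,11,Ca,1.53
basil,11,Mg,0.36
basil,11,B,16.1
basil,12,Fe,194.89
basil,12,Zn,25.61
basil,12,Cu,7.27
basil,12,Mn,34.15
basil,12,N,1.82
basil,12,P,0.25
basil,12,K,1.69
basil,12,Ca,2.25
basil,12,Mg,0.54
basil,12,B,23.8
basil,13,Fe,177.34
basil,13,Zn,22.8
basil,13,Cu,6.47
basil,13,Mn,31.67
basil,13,N,1.62
basil,13,P,0.22
basil,13,K,1.37
basil,13,Ca,2.36
basil,13,Mg,0.48
basil,13,B,22.3
basil,14,Fe,178.53
basil,14,Zn,24.35
basil,14,Cu,6.91
basil,14,Mn,35.47
basil,14,N,1.73
basil,14,P,0.21
basil,14,K,1.47
basil,14,Ca,2.41
basil,14,Mg,0.51
basil,14,B,24.9
basil,15,Fe,192.96
basil,15,Zn,26.04
basil,15,Cu,7.39
basil,15,Mn,40.53
basil,15,N,1.85
basil,15,P,0.25
basil,15,K,1.59
basil,15,Ca,2.6
basil,15,Mg,0.55
basil,15,B,28.35
basil,16,Fe,115.99
basil,16,Zn,17.67
basil,16,Cu,5.02
basil,16,Mn,23.57
basil,16,N,1.26
basil,16,P,0.17
basil,16,K,1.16
basil,16,Ca,1.56
basil,16,Mg,0.37
basil,16,B,16.5
basil,17,Fe,101.6
basil,17,Zn,15.48
basil,17,Cu,4.39
basil,17,Mn,20.64
basil,17,N,1.1
basil,17,P,0.15
basil,17,K,1.02
basil,17,Ca,1.2
basil,17,Mg,0.33
basil,17,B,14.5
basil,18,Fe,148.06
basil,18,Zn,22.56
basil,18,Cu,6.4
basil,18,Mn,30.08
basil,18,N,1.6
basil,18,P,0.22
basil,18,K,1.48
basil,18,Ca,2.0
basil,18,Mg,0.47
basil,18,B,21.12
basil,19,Fe,166.77
basil,19,Zn,25.41
basil,19,Cu,7.21
basil,19,Mn,33.88
basil,19,N,1.81
basil,19,P,0.24
basil,19,K,1.67
basil,19,Ca,2.25
basil,19,Mg,0.53
basil,19,B,13.8
basil,20,Fe,136.84
basil,20,Zn,20.85
basil,20,Cu,5.92
basil,20,Mn,27.8
basil,20,N,1.48
basil,20,P,0.2
basil,20,K,1.37
basil,20,Ca,1.85
basil,20,Mg,0.44
basil,20,B,19.5
basil,21,Fe,201.52
basil,21,Zn,16.47
basil,21,Cu,4.67
basil,21,Mn,21.96
basil,21,N,1.17
basil,21,P,0.16
basil,21,K,1.08
basil,21,Ca,2.72
basil,21,Mg,0.35
basil,21,B,15.4
basil,22,Fe,132.03
basil,22,Zn,20.12
basil,22,Cu,5.71
basil,22,Mn,26.82
basil,22,N,1.43
basil,22,P,0.19
basil,22,K,1.32
basil,22,Ca,1.78
basil,22,Mg,0.42
basil,22,B,15.87
basil,23,Fe,124.01
basil,23,Zn,18.9
basil,23,Cu,5.36
basil,23,Mn,25.19
basil,23,N,1.34
basil,23,P,0.18
basil,23,K,1.24
basil,23,Ca,1.67
basil,23,Mg,0.4
basil,23,B,17.7
basil,24,Fe,155.55
basil,24,Zn,22.24
basil,24,Cu,6.31
basil,24,Mn,29.65
basil,24,N,1.58
basil,24,P,0.21
basil,24,K,1.46
basil,24,Ca,2.1
basil,24,Mg,0.47
basil,24,B,20.82
basil,25,Fe,158.87
basil,25,Zn,21.39
basil,25,Cu,6.07
basil,25,Mn,28.52
basil,25,N,1.52
basil,25,P,0.2
basil,25,K,1.34
basil,25,Ca,2.25
basil,25,Mg,0.45
basil,25,B,20.1
basil,26,Fe,158.75
basil,26,Zn,18.44
basil,26,Cu,5.23
basil,26,Mn,24.58
basil,26,N,1.31
basil,26,P,0.18
basil,26,K,1.15
basil,26,Ca,2.14
basil,26,Mg,0.39
basil,26,B,17.3
basil,27,Fe,178.53
basil,27,Zn,23.5
basil,27,Cu,6.67
basil,27,Mn,31.34
basil,27,N,1.67
basil,27,P,0.22
basil,27,K,1.48
basil,27,Ca,2.41
basil,27,Mg,0.49
basil,27,B,22.0
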