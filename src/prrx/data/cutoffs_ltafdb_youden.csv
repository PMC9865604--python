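kind,x,cutoff
percent,0.25,94.35
percent,0.5,94.35
percent,0.75,93.86
percent,1,91.22
percent,1.25,88.71
percent,1.5,87.32
percent,1.75,85.84
percent,2,83.76
percent,2.25,80.45
percent,2.5,79.81
percent,2.75,78.20
percent,3,77.19
percent,3.25,75.32
percent,3.5,74.19
percent,3.75,72.31
percent,4,71.17
percent,4.25,68.03
percent,4.5,66.34
percent,4.75,67.55
percent,5,64.33
percent,5.25,64.47
percent,5.5,62.66
percent,5.75,62.02
percent,6,61.64
percent,6.25,59.63
percent,6.5,56.64
percent,6.75,55.97
percent,7,53.95
percent,7.25,53.95
percent,7.5,53.42
percent,7.75,52.45
percent,8,52.20
percent,8.25,49.03
percent,8.5,49.01
percent,8.75,48.28
percent,9,46.53
percent,9.25,45.75
percent,9.5,45.60
percent,9.75,45.00
percent,10,43.05
percent,10.25,43.06
percent,10.5,42.61
percent,10.75,41.25
percent,11,40.28
percent,11.25,39.39
percent,11.5,39.34
percent,11.75,38.60
percent,12,36.42
percent,12.25,36.62
percent,12.5,36.42
percent,12.75,36.18
percent,13,34.84
percent,13.25,34.71
percent,13.5,33.54
percent,13.75,32.63
percent,14,32.61
percent,14.25,32.61
percent,14.5,31.00
percent,14.75,31.00
percent,15,30.94
percent,15.25,29.66
percent,15.5,29.14
percent,15.75,28.28
percent,16,28.10
percent,16.25,28.14
percent,16.5,26.11
percent,16.75,26.11
percent,17,25.15
percent,17.25,24.78
percent,17.5,24.73
percent,17.75,24.81
percent,18,24.81
percent,18.25,23.76
percent,18.5,23.66
percent,18.75,23.57
percent,19,22.07
percent,19.25,22.12
percent,19.5,22.12
percent,19.75,22.07
percent,20,21.90
percent,20.25,21.19
percent,20.5,20.95
percent,20.75,21.19
percent,21,19.38
percent,21.25,19.42
percent,21.5,18.62
percent,21.75,19.38
percent,22,17.69
percent,22.25,18.25
percent,22.5,18.24
percent,22.75,16.41
percent,23,16.03
percent,23.25,16.08
percent,23.5,16.41
percent,23.75,16.38
percent,24,16.03
percent,24.25,15.71
percent,24.5,15.44
percent,24.75,15.27
percent,25,15.27
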