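subject,point,pao2,paco2,sao2
1,A,88.2,30.5,98
1,B,119.6,30.6,99
1,C,106.5,49.5,97
1,D,48.6,42.2,77
1,F,214.6,34.9,99
1,G,35.4,31.3,61
2,A,123.8,30.8,98
2,B,146.8,20.3,99
2,C,235.6,33.3,100
2,D,63.2,32.8,90
2,F,170.6,30.4,100
2,G,49.6,25.4,83
3,A,104.6,29.4,99
3,B,135.9,21.5,99
3,C,155.4,37.9,99
3,D,36.6,34.9,62
3,F,325.4,37.7,99
3,G,48.4,37.5,79
4,A,102.3,36.8,98
4,B,123.6,32.9,99
4,C,110,40.1,98
4,D,33.3,41.1,52
4,F,116.2,42.5,98
4,G,29.1,39.4,41
5,A,87.9,29.2,99
5,B,139.8,19.8,99
5,C,194.1,35.5,99
5,D,56.3,30.5,86
5,F,229.1,27.1,99
5,G,40.9,27.1,68
6,A,102.4,34.4,99
6,B,142.6,22.7,100
6,C,196.4,38.6,99
6,D,52.5,36.5,82
6,F,144.2,41.7,100
6,G,35.1,38.9,50
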