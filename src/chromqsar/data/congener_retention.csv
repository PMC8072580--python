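compound_id,system,x_kind,x,k
1,MLC,surfactant_molarity,0.075,13.73
1,MLC,surfactant_molarity,0.1,12.03
1,MLC,surfactant_molarity,0.125,10.47
1,MLC,surfactant_molarity,0.15,10.53
2,MLC,surfactant_molarity,0.075,25.51
2,MLC,surfactant_molarity,0.1,21.45
2,MLC,surfactant_molarity,0.125,18.25
2,MLC,surfactant_molarity,0.15,17.34
3,MLC,surfactant_molarity,0.075,8.98
3,MLC,surfactant_molarity,0.1,8.18
3,MLC,surfactant_molarity,0.125,7.46
3,MLC,surfactant_molarity,0.15,7.2
4,MLC,surfactant_molarity,0.075,39.84
4,MLC,surfactant_molarity,0.1,31.65
4,MLC,surfactant_molarity,0.125,24.39
4,MLC,surfactant_molarity,0.15,22.52
5,MLC,surfactant_molarity,0.075,41.53
5,MLC,surfactant_molarity,0.1,33.76
5,MLC,surfactant_molarity,0.125,26.18
5,MLC,surfactant_molarity,0.15,24.1
6,MLC,surfactant_molarity,0.075,60.81
6,MLC,surfactant_molarity,0.1,46.76
6,MLC,surfactant_molarity,0.125,34.01
6,MLC,surfactant_molarity,0.15,29.82
7,MLC,surfactant_molarity,0.075,14.11
7,MLC,surfactant_molarity,0.1,12.22
7,MLC,surfactant_molarity,0.125,10.72
7,MLC,surfactant_molarity,0.15,10.02
8,MLC,surfactant_molarity,0.075,6.5
8,MLC,surfactant_molarity,0.1,5.97
8,MLC,surfactant_molarity,0.125,5.52
8,MLC,surfactant_molarity,0.15,5.28
9,MLC,surfactant_molarity,0.075,25.67
9,MLC,surfactant_molarity,0.1,21.44
9,MLC,surfactant_molarity,0.125,17.64
9,MLC,surfactant_molarity,0.15,16.14
10,MLC,surfactant_molarity,0.075,5.89
10,MLC,surfactant_molarity,0.1,5.4
10,MLC,surfactant_molarity,0.125,5.04
10,MLC,surfactant_molarity,0.15,4.79
11,MLC,surfactant_molarity,0.075,10.61
11,MLC,surfactant_molarity,0.1,9.36
11,MLC,surfactant_molarity,0.125,8.27
11,MLC,surfactant_molarity,0.15,7.66
12,MLC,surfactant_molarity,0.075,36.9
12,MLC,surfactant_molarity,0.1,29.09
12,MLC,surfactant_molarity,0.125,22.17
12,MLC,surfactant_molarity,0.15,19.83
13,MLC,surfactant_molarity,0.075,41.71
13,MLC,surfactant_molarity,0.1,32.28
13,MLC,surfactant_molarity,0.125,25.32
13,MLC,surfactant_molarity,0.15,22.45
14,MLC,surfactant_molarity,0.075,59.61
14,MLC,surfactant_molarity,0.1,44.28
14,MLC,surfactant_molarity,0.125,32.68
14,MLC,surfactant_molarity,0.15,28.56
15,MLC,surfactant_molarity,0.075,2.09
15,MLC,surfactant_molarity,0.1,1.9
15,MLC,surfactant_molarity,0.125,1.81
15,MLC,surfactant_molarity,0.15,1.84
16,MLC,surfactant_molarity,0.075,4.49
16,MLC,surfactant_molarity,0.1,4.04
16,MLC,surfactant_molarity,0.125,3.81
16,MLC,surfactant_molarity,0.15,3.75
17,MLC,surfactant_molarity,0.075,10.12
17,MLC,surfactant_molarity,0.1,8.72
17,MLC,surfactant_molarity,0.125,8.0
17,MLC,surfactant_molarity,0.15,8.0
18,MLC,surfactant_molarity,0.075,9.94
18,MLC,surfactant_molarity,0.1,8.48
18,MLC,surfactant_molarity,0.125,7.53
18,MLC,surfactant_molarity,0.15,7.75
19,MLC,surfactant_molarity,0.075,24.39
19,MLC,surfactant_molarity,0.1,18.98
19,MLC,surfactant_molarity,0.125,14.97
19,MLC,surfactant_molarity,0.15,14.81
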