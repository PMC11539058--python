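number,temperature,ionic_strength,pH,tm,ln_v
1,277,0,3.5,73.7,-5.95
2,338,100,3.5,62.5,9.01
3,338,200,3.5,60.6,9.64
4,277,50,3.5,64.9,-4.38
5,277,150,3.5,61.8,-5.36
6,338,250,3.5,59.5,9.88
7,338,150,3.5,61.8,9.59
8,338,50,3.5,64.9,9.32
9,318,250,3.5,59.5,1.38
10,296,250,3.5,59.5,-3.81
11,296,250,4.5,73.1,-4.19
12,318,150,4.5,73.3,-3.07
13,338,0,4.5,83.2,0.43
14,338,200,4.5,71.9,7.09
15,338,250,4.5,73.1,6.85
16,318,50,4.5,75.0,-3.20
17,296,50,4.5,75.0,-4.12
18,338,50,4.5,75.0,4.90
19,338,100,4.5,74.0,5.60
20,338,150,4.5,73.3,6.54
21,277,250,4.5,73.1,-3.59
22,296,250,5.5,80.7,-3.76
23,296,100,5.5,81.3,-3.68
24,296,0,5.5,79.6,-2.96
25,296,200,5.5,80.3,-3.70
26,296,150,5.5,80.4,-4.09
27,296,50,5.5,79.7,-3.61
28,318,250,7,77.9,-2.71
29,296,50,7,78.0,-4.65
30,296,250,7,77.9,-6.08
31,338,0,7,78.5,0.98
32,318,150,7,78.6,-2.81
33,338,50,7,78.0,0.98
34,277,250,7,77.9,-4.86
35,296,50,7,78.0,-4.65
36,277,150,7,78.6,-5.32
37,296,150,7,78.6,-4.02
38,338,0,8,77.9,1.62
39,338,500,8,77.1,1.83
40,338,400,8,77.2,2.05
41,277,100,8,77.3,-4.82
42,338,300,8,77.9,2.08
43,338,200,8,77.9,2.18
44,338,200,9,77.4,2.47
45,338,100,9,76.7,2.84
46,338,500,9,76.8,2.80
47,338,400,9,76.8,2.86
48,338,0,9,76.5,2.06
49,338,300,9,76.9,2.83
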