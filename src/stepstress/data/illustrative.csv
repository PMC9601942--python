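# Illustrative step-stress competing-risks dataset (simulated).
# True rates: lambda11=1.0, lambda12=1.5, lambda21=2.0, lambda22=3.0.
# Four units withdrawn at the last failure of each stage (stage-end convention).
# n=30
# N1=10
# N2=12
index,time,cause,removed
1,0.00638,2,0
2,0.01442,1,0
3,0.01738,1,0
4,0.02380,2,0
5,0.04067,2,0
6,0.05375,2,0
7,0.06667,1,0
8,0.08122,1,0
9,0.11568,2,0
10,0.15354,2,4
11,0.17226,1,0
12,0.18334,2,0
13,0.20501,2,0
14,0.21434,1,0
15,0.21518,2,0
16,0.22165,1,0
17,0.23910,1,0
18,0.24391,1,0
19,0.26104,2,0
20,0.32582,2,0
21,0.34505,2,0
22,0.65557,2,4
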