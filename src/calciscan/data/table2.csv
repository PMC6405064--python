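group,specimen_id,genetic_type,d13c,d18o,weight
A,11-D1,,-0.22,-1.35,6.1
A,11-D2,,+0.10,-1.43,8.2
A,11-D3,,-0.49,-1.69,5.2
A,11-D4,,-0.20,-1.17,4.2
A,11-D6,,-0.62,-1.19,3.6
A,11-D7,,-0.65,-2.08,3.0
A,11-D8,,-0.60,-1.71,1.7
A,11-D9,,-1.20,-0.65,1.4
A,11-D10,,-1.11,-1.46,1.2
A,11-D15,,-0.60,-2.28,1.1
A,11-D16,,-0.29,-1.95,1.5
A,11-D20,,-0.92,-2.38,4.1
A,11-D21,,-0.58,-1.63,3.9
A,11-D22,,-0.35,-1.80,2.4
B,12-2,Ia,-0.40,-1.74,6.1
B,12-3,Ia,-0.19,-1.61,4.9
B,12-4,Ia,-0.52,-2.12,3.0
B,12-5,Ia,-0.12,-1.91,5.3
B,12-11,IIa,-0.62,-1.92,2.4
B,12-12,IIa,+0.05,-1.64,4.7
B,12-13,IIa,+0.00,-1.65,3.8
B,12-15,Ib,-0.59,-2.12,2.6
B,12-16,IIa,-0.11,-1.83,3.9
B,12-17,IIa,-0.29,-1.52,6.7
B,12-18,,-0.17,-2.62,4.1
B,12-19,Ib,-0.52,-1.99,1.4
B,12-20,Ib,-0.47,-2.36,3.0
B,12-21,Ib,-0.35,-2.25,1.8
B,12-22,Ia,-0.58,-2.10,2.4
B,12-23,Ia,-0.45,-2.08,1.7
B,12-36,Ib,-0.78,-1.88,1.5
B,12-39,IIa,-0.72,-2.16,1.5
B,12-40,Ib,-0.77,-1.83,1.4
B,12-41,Ia,-0.39,-1.60,1.4
C,12-6,Ia,-0.43,-2.01,3.8
C,12-7,IIa,+0.13,-1.56,7.6
C,12-8,IIa,-0.05,-1.76,6.1
C,12-9,IIa,+0.34,-1.47,6.7
C,12-10,IIa,-0.24,-2.48,5.3
C,12-24,Ia,-0.45,-1.90,2.0
C,12-25,Ia,-0.32,-1.70,1.7
C,12-26,Ia,-0.88,-1.76,1.8
C,12-28,Ib,-0.37,-1.82,2.7
C,12-30,Ia,-0.70,-1.48,2.0
C,12-32,Ib,-0.52,-1.89,1.4
C,12-33,IIa,+0.09,-2.94,5.5
C,12-34,Ia,-0.32,-2.19,2.9
C,12-35,Ia,-0.75,-1.82,1.5
C,12-36,Ia,-0.72,-1.86,1.5
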