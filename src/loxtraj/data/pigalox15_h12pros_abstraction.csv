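# description: pigALOX15-mini-LOX H12proS abstraction ensemble (10 QM/MM snapshots)
# printed_exponential_average: 17.6
# temperature_K: 300
frame_id,d_react,dE_barrier,dE_reaction,stereo
940,3.2,20.9,-12.5,ZZ
1548,3.0,19.8,-11.8,ZZ
1709,2.9,24.5,-12.4,ZZ
2132,2.8,22.1,-9.7,ZZ
2515,3.2,27.2,-8.9,ZZ
3020,2.8,19.8,-10.8,ZZ
3556,3.2,24.5,-9.9,ZZ
4502,2.7,15.9,-16.1,ZZ
5758,2.6,20.4,-12.1,ZZ
9207,2.6,22.6,-13.1,ZZ
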