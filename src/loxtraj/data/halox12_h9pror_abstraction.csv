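# description: hALOX12 H9proR abstraction ensemble (10 QM/MM snapshots)
# printed_exponential_average: 23.9
# temperature_K: 300
frame_id,d_react,dE_barrier,dE_reaction,stereo
322,3.5,36.4,-13.9,ZZ
2253,3.5,23.4,-19.1,ZZ
4986,5.0,35.0,-14.1,ZZ
6993,3.1,29.7,-14.5,ZZ
8721,3.3,22.7,-13.6,ZZ
10106,3.4,25.6,-17.4,ZZ
12860,3.9,29.2,-15.3,ZZ
14423,3.4,27.5,-13.6,ZZ
18168,3.3,31.8,-13.8,ZZ
19729,3.9,43.7,-18.4,ZZ
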