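# description: hALOX12 H12proS abstraction ensemble (10 QM/MM snapshots)
# printed_exponential_average: 17.1
# temperature_K: 300
frame_id,d_react,dE_barrier,dE_reaction,stereo
322,3.5,15.9,-18.3,ZE
2253,5.4,20.5,-19.0,ZE
4986,5.4,19.3,-17.0,ZE
6993,3.9,18.0,-18.5,ZE
8721,5.0,21.9,-17.3,ZE
10106,5.5,24.3,-16.8,ZE
12860,5.2,22.9,-18.5,ZE
14423,4.1,21.8,-19.1,ZE
18168,3.7,17.1,-17.0,ZE
19729,3.4,17.1,-17.0,ZE
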