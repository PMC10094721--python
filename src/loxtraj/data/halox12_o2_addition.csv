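# description: hALOX12 O2 addition / rotation / retro-H abstraction pathways (3 converged snapshots)
# temperature_K: 300
frame_id,d_O_C14_react,dE_barrier,chirality,geometry,dE_rotation,dE_reorg,dE_retro_H
8721,3.2,3.0,S,Antarafacial,6.6,10.2,33.3
10106,3.2,4.3,S,Antarafacial,5.8,,
18168,3.1,3.1,S,Antarafacial,5.9,13.1,20.6
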