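index,name,abbrev,subsystem,mni_x,mni_y,mni_z,radius
1,Anterior medial prefrontal cortex,aMPFC,core,-6,52,-2,10
2,Posterior cingulate cortex,PCC,core,-8,-56,26,10
3,Dorsal medial prefrontal cortex,dMPFC,dMPFC,0,52,26,10
4,Left temporal parietal junction,lTPJ,dMPFC,-54,-54,28,10
5,Left lateral temporal cortex,lLTC,dMPFC,-60,-24,-18,10
6,Left temporal pole,lTempP,dMPFC,-50,14,-40,10
7,Right temporal parietal junction,rTPJ,dMPFC,54,-54,28,10
8,Right lateral temporal cortex,rLTC,dMPFC,60,-24,-18,10
9,Right temporal pole,rTempP,dMPFC,50,14,-40,10
10,Ventral medial prefrontal cortex,vMPFC,MTL,0,26,-18,10
11,Left posterior inferior parietal lobule,lpIPL,MTL,-44,-74,32,10
12,Left retrosplenial cortex,lRsp,MTL,-14,-52,8,10
13,Left parahippocampal cortex,lPHC,MTL,-28,-40,-12,10
14,Left hippocampal formation,lHF+,MTL,-22,-20,-26,10
15,Right posterior inferior parietal lobule,rpIPL,MTL,44,-74,32,10
16,Right retrosplenial cortex,rRsp,MTL,14,-52,8,10
17,Right parahippocampal cortex,rPHC,MTL,28,-40,-12,10
18,Right hippocampal formation,rHF+,MTL,22,-20,-26,10
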