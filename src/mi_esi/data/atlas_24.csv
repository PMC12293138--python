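id,name,hemisphere,x,y,z,surface
1,SACL,L,-0.275776416,-0.413664624,0.689441040,1
2,S1FL,L,-0.070459701,-0.132111939,0.836708949,1
3,S1HL,L,-0.431028670,-0.143676223,0.718381117,1
4,S2L,L,-0.790483943,-0.098810493,0.296431479,1
5,CMAL,L,-0.058431704,0.097386173,0.486930867,0
6,M1FL,L,-0.071228599,0.044517874,0.845839610,1
7,M1HL,L,-0.436608561,0.048512062,0.727680936,1
8,M1LL,L,-0.757908830,0.151581766,0.353690787,1
9,SMAL,L,-0.071424789,0.267842958,0.803528873,1
10,pSMAL,L,-0.072845065,0.500809822,0.682922484,1
11,PMdL,L,-0.386838484,0.338483674,0.676967348,1
12,PMvL,L,-0.653400198,0.452353983,0.301569322,1
13,SACR,R,0.275776416,-0.413664624,0.689441040,1
14,S1FR,R,0.070459701,-0.132111939,0.836708949,1
15,S1HR,R,0.431028670,-0.143676223,0.718381117,1
16,S2R,R,0.790483943,-0.098810493,0.296431479,1
17,CMAR,R,0.058431704,0.097386173,0.486930867,0
18,M1FR,R,0.071228599,0.044517874,0.845839610,1
19,M1HR,R,0.436608561,0.048512062,0.727680936,1
20,M1LR,R,0.757908830,0.151581766,0.353690787,1
21,SMAR,R,0.071424789,0.267842958,0.803528873,1
22,pSMAR,R,0.072845065,0.500809822,0.682922484,1
23,PMdR,R,0.386838484,0.338483674,0.676967348,1
24,PMvR,R,0.653400198,0.452353983,0.301569322,1
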