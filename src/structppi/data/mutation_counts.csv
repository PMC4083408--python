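protein,pdb_chain,mutation_count
A2M,2p9rA,16
A2M,1bv8A,7
A2M,4acqC,139
ADAMTS1,2jihB,34
AMBP,4es7A,12
ANXA6,1m9iA,35
APOE,2kc3A,5
APOE,2l7bA,8
APP,1tknA,13
APP,3ktmE,9
APP,2llmA,5
APP,3nylA,21
APP,1owtA,6
APP,3umkA,20
B2M,1ypzB,22
B2M,3ov6A,29
BTRC,1p22A,30
CPB2,3d68A,33
CTSB,3pbhA,22
ERBB4,2ahxB,121
IL10,2ilkA,12
IL10RA,1lqsR,25
IL10RB,3lqmA,24
IL1B,3ltqA,16
IL28B,3hhcB,21
IL4,1bbnA,9
KLK3,2zchP,29
LEP,1ax8A,11
LRP1,2knyA,7
LYZ,1lz6A,6
MMP2,3ayuA,20
NGF,1wwwW,10
PDGFA,3mjkA,6
SHBG,1kdkA,6
SIRPG,2jjwA,12
TGFBI,1x3bA,15
TP63,2y9tA,8
TP63,2rmnA,29
TP63,4a9zC,5
UBC,3b0aD,21
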