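label,x,y
Fp1,-0.284296,0.874972
AF7,-0.540762,0.744296
AF3,-0.312738,0.670668
F1,-0.187303,0.463592
F3,-0.377592,0.466288
F5,-0.566032,0.492044
F7,-0.744296,0.540762
FT7,-0.874972,0.284296
FC5,-0.672178,0.258025
FC3,-0.441474,0.234736
FC1,-0.226274,0.226274
C1,-0.230000,-0.000000
C3,-0.460000,-0.000000
C5,-0.690000,-0.000000
T7,-0.920000,-0.000000
TP7,-0.874972,-0.284296
CP5,-0.672178,-0.258025
CP3,-0.441474,-0.234736
CP1,-0.226274,-0.226274
P1,-0.187303,-0.463592
P3,-0.377592,-0.466288
P5,-0.566032,-0.492044
P7,-0.744296,-0.540762
P9,-0.930370,-0.675953
PO7,-0.540762,-0.744296
PO3,-0.312738,-0.670668
O1,-0.284296,-0.874972
Iz,0.000000,-1.150000
Oz,0.000000,-0.920000
POz,0.000000,-0.690000
Pz,0.000000,-0.460000
CPz,0.000000,-0.230000
Fpz,0.000000,0.920000
Fp2,0.284296,0.874972
AF8,0.540762,0.744296
AF4,0.312738,0.670668
AFz,0.000000,0.690000
Fz,0.000000,0.460000
F2,0.187303,0.463592
F4,0.377592,0.466288
F6,0.566032,0.492044
F8,0.744296,0.540762
FT8,0.874972,0.284296
FC6,0.672178,0.258025
FC4,0.441474,0.234736
FC2,0.226274,0.226274
FCz,0.000000,0.230000
Cz,0.000000,0.000000
C2,0.230000,0.000000
C4,0.460000,0.000000
C6,0.690000,0.000000
T8,0.920000,0.000000
TP8,0.874972,-0.284296
CP6,0.672178,-0.258025
CP4,0.441474,-0.234736
CP2,0.226274,-0.226274
P2,0.187303,-0.463592
P4,0.377592,-0.466288
P6,0.566032,-0.492044
P8,0.744296,-0.540762
P10,0.930370,-0.675953
PO8,0.540762,-0.744296
PO4,0.312738,-0.670668
O2,0.284296,-0.874972
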