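lead_name,x,y
Fp1,-0.274778,0.783327
Fpz,0.001019,0.800410
Fp2,0.275547,0.783092
AF7,-0.531544,0.664649
AF3,-0.267474,0.609838
AFz,0.001668,0.582641
AF4,0.277295,0.603518
AF8,0.531737,0.664458
F7,-0.736153,0.445008
F5,-0.550264,0.410017
F3,-0.362299,0.382975
F1,-0.177028,0.366544
Fz,0.001939,0.363343
F2,0.189837,0.370499
F4,0.372856,0.390612
F6,0.559579,0.410571
F8,0.735499,0.447299
FT7,-0.845750,0.147846
FC5,-0.622401,0.150277
FC3,-0.404290,0.152603
FC1,-0.196771,0.150262
FCz,0.002071,0.150802
FC2,0.202853,0.154180
FC4,0.411740,0.156801
FC6,0.625493,0.156784
FT8,0.843870,0.159013
T7,-0.830426,-0.158058
C5,-0.608722,-0.104333
C3,-0.396887,-0.070634
C1,-0.192072,-0.053035
Cz,0.002007,-0.045901
C2,0.202055,-0.051619
C4,0.406881,-0.066080
C6,0.615823,-0.094277
T8,0.832830,-0.147031
TP7,-0.727246,-0.394542
CP5,-0.541783,-0.316870
CP3,-0.355282,-0.262781
CP1,-0.173709,-0.231323
CPz,0.001823,-0.223566
CP2,0.187702,-0.230194
CP4,0.367839,-0.257536
CP6,0.552337,-0.305604
TP8,0.730525,-0.388924
P9,-0.689384,-0.696527
P7,-0.563670,-0.571595
P5,-0.432330,-0.490288
P3,-0.291767,-0.433670
P1,-0.142880,-0.402002
Pz,0.001564,-0.390708
P2,0.156936,-0.395721
P4,0.302549,-0.426975
P6,0.436765,-0.488341
P8,0.567766,-0.567864
P10,0.690061,-0.694689
PO7,-0.381364,-0.678215
PO3,-0.211985,-0.585552
POz,0.001180,-0.559168
PO4,0.214529,-0.588202
PO8,0.385580,-0.676210
O1,-0.190410,-0.727947
Oz,0.000681,-0.726774
O2,0.193506,-0.727245
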