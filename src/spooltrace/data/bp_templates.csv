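# Idealized Watson-Crick base-pair templates, one row per heavy atom.
# Frame: origin at the pair center, z along the helix axis, y along C1'B->C1'A.
# Built from CCD ideal nucleotide coordinates placed in a standard base-pair
# reference frame; glycosidic torsions tuned for straight-helix backbone
# continuity (rise 0.34 nm, twist 36 deg). Units: nm. Version 1.
pair,strand,res_name,atom_name,element,x_nm,y_nm,z_nm
A,A,DA,N9,N,-0.129000,0.450000,0.000000
A,A,DA,C8,C,0.000302,0.492751,-0.000124
A,A,DA,N7,N,0.080889,0.390587,-0.000176
A,A,DA,C5,C,0.008580,0.276034,0.000477
A,A,DA,C6,C,0.040170,0.139167,-0.000155
A,A,DA,N6,N,0.171959,0.096927,-0.000278
A,A,DA,N1,N,-0.059427,0.051155,-0.000086
A,A,DA,C2,C,-0.185338,0.090534,-0.000053
A,A,DA,N3,N,-0.219732,0.217552,-0.000025
A,A,DA,C4,C,-0.127043,0.312851,-0.000086
A,A,DA,P,P,0.005982,0.924673,-0.011510
A,A,DA,OP1,O,-0.010293,1.048508,-0.090863
A,A,DA,OP2,O,0.013631,0.798017,-0.110558
A,A,DA,O5',O,-0.119510,0.907712,0.087824
A,A,DA,C5',C,-0.236322,0.900446,0.005984
A,A,DA,C4',C,-0.297348,0.760552,0.016350
A,A,DA,O4',O,-0.216461,0.663919,-0.054591
A,A,DA,C3',C,-0.294071,0.710239,0.162858
A,A,DA,O3',O,-0.408908,0.755293,0.234959
A,A,DA,C2',C,-0.297280,0.556688,0.144428
A,A,DA,C1',C,-0.248412,0.534964,-0.000042
A,B,DT,N1,N,-0.129000,-0.450000,0.000000
A,B,DT,C2,C,-0.139316,-0.309247,-0.000025
A,B,DT,O2,O,-0.246445,-0.248320,0.000011
A,B,DT,N3,N,-0.017275,-0.240916,-0.000048
A,B,DT,C4,C,0.109628,-0.296820,0.000025
A,B,DT,O4,O,0.213043,-0.230628,0.000123
A,B,DT,C5,C,0.112394,-0.445514,-0.000051
A,B,DT,C7,C,0.245582,-0.513414,-0.000093
A,B,DT,C6,C,-0.004322,-0.511237,-0.000019
A,B,DT,P,P,0.005982,-0.924673,0.011510
A,B,DT,OP1,O,-0.010293,-1.048508,0.090863
A,B,DT,OP2,O,0.013631,-0.798017,0.110558
A,B,DT,O5',O,-0.119510,-0.907712,-0.087824
A,B,DT,C5',C,-0.236322,-0.900446,-0.005984
A,B,DT,C4',C,-0.297348,-0.760552,-0.016350
A,B,DT,O4',O,-0.216461,-0.663919,0.054591
A,B,DT,C3',C,-0.294071,-0.710239,-0.162858
A,B,DT,O3',O,-0.408908,-0.755293,-0.234959
A,B,DT,C2',C,-0.297280,-0.556688,-0.144428
A,B,DT,C1',C,-0.248412,-0.534964,0.000042
T,A,DT,N1,N,-0.129000,0.450000,0.000000
T,A,DT,C2,C,-0.139316,0.309247,0.000025
T,A,DT,O2,O,-0.246445,0.248320,-0.000011
T,A,DT,N3,N,-0.017275,0.240916,0.000048
T,A,DT,C4,C,0.109628,0.296820,-0.000025
T,A,DT,O4,O,0.213043,0.230628,-0.000123
T,A,DT,C5,C,0.112394,0.445514,0.000051
T,A,DT,C7,C,0.245582,0.513414,0.000093
T,A,DT,C6,C,-0.004322,0.511237,0.000019
T,A,DT,P,P,0.005982,0.924673,-0.011510
T,A,DT,OP1,O,-0.010293,1.048508,-0.090863
T,A,DT,OP2,O,0.013631,0.798017,-0.110558
T,A,DT,O5',O,-0.119510,0.907712,0.087824
T,A,DT,C5',C,-0.236322,0.900446,0.005984
T,A,DT,C4',C,-0.297348,0.760552,0.016350
T,A,DT,O4',O,-0.216461,0.663919,-0.054591
T,A,DT,C3',C,-0.294071,0.710239,0.162858
T,A,DT,O3',O,-0.408908,0.755293,0.234959
T,A,DT,C2',C,-0.297280,0.556688,0.144428
T,A,DT,C1',C,-0.248412,0.534964,-0.000042
T,B,DA,N9,N,-0.129000,-0.450000,0.000000
T,B,DA,C8,C,0.000302,-0.492751,0.000124
T,B,DA,N7,N,0.080889,-0.390587,0.000176
T,B,DA,C5,C,0.008580,-0.276034,-0.000477
T,B,DA,C6,C,0.040170,-0.139167,0.000155
T,B,DA,N6,N,0.171959,-0.096927,0.000278
T,B,DA,N1,N,-0.059427,-0.051155,0.000086
T,B,DA,C2,C,-0.185338,-0.090534,0.000053
T,B,DA,N3,N,-0.219732,-0.217552,0.000025
T,B,DA,C4,C,-0.127043,-0.312851,0.000086
T,B,DA,P,P,0.005982,-0.924673,0.011510
T,B,DA,OP1,O,-0.010293,-1.048508,0.090863
T,B,DA,OP2,O,0.013631,-0.798017,0.110558
T,B,DA,O5',O,-0.119510,-0.907712,-0.087824
T,B,DA,C5',C,-0.236322,-0.900446,-0.005984
T,B,DA,C4',C,-0.297348,-0.760552,-0.016350
T,B,DA,O4',O,-0.216461,-0.663919,0.054591
T,B,DA,C3',C,-0.294071,-0.710239,-0.162858
T,B,DA,O3',O,-0.408908,-0.755293,-0.234959
T,B,DA,C2',C,-0.297280,-0.556688,-0.144428
T,B,DA,C1',C,-0.248412,-0.534964,0.000042
G,A,DG,N9,N,-0.129000,0.450000,0.000000
G,A,DG,C8,C,0.000469,0.492906,0.000026
G,A,DG,N7,N,0.080921,0.390585,-0.000082
G,A,DG,C5,C,0.008068,0.276293,-0.000179
G,A,DG,C6,C,0.040694,0.138653,-0.000309
G,A,DG,O6,O,0.156960,0.102072,-0.000366
G,A,DG,N1,N,-0.060206,0.048861,0.000356
G,A,DG,C2,C,-0.189773,0.090858,-0.000189
G,A,DG,N2,N,-0.290146,-0.002649,-0.000290
G,A,DG,N3,N,-0.221383,0.218410,-0.000199
G,A,DG,C4,C,-0.126976,0.313201,-0.000005
G,A,DG,P,P,0.005982,0.924673,-0.011510
G,A,DG,OP1,O,-0.010293,1.048508,-0.090863
G,A,DG,OP2,O,0.013631,0.798017,-0.110558
G,A,DG,O5',O,-0.119510,0.907712,0.087824
G,A,DG,C5',C,-0.236322,0.900446,0.005984
G,A,DG,C4',C,-0.297348,0.760552,0.016350
G,A,DG,O4',O,-0.216461,0.663919,-0.054591
G,A,DG,C3',C,-0.294071,0.710239,0.162858
G,A,DG,O3',O,-0.408908,0.755293,0.234959
G,A,DG,C2',C,-0.297280,0.556688,0.144428
G,A,DG,C1',C,-0.248412,0.534964,-0.000042
G,B,DC,N1,N,-0.129000,-0.450000,0.000000
G,B,DC,C2,C,-0.142139,-0.316203,-0.000047
G,B,DC,O2,O,-0.253728,-0.266853,-0.000250
G,B,DC,N3,N,-0.035312,-0.236631,0.000027
G,B,DC,C4,C,0.087102,-0.287560,0.000156
G,B,DC,N4,N,0.196725,-0.204438,0.000173
G,B,DC,C5,C,0.104242,-0.427478,-0.000200
G,B,DC,C6,C,-0.005261,-0.507010,0.000186
G,B,DC,P,P,0.005982,-0.924673,0.011510
G,B,DC,OP1,O,-0.010293,-1.048508,0.090863
G,B,DC,OP2,O,0.013631,-0.798017,0.110558
G,B,DC,O5',O,-0.119510,-0.907712,-0.087824
G,B,DC,C5',C,-0.236322,-0.900446,-0.005984
G,B,DC,C4',C,-0.297348,-0.760552,-0.016350
G,B,DC,O4',O,-0.216461,-0.663919,0.054591
G,B,DC,C3',C,-0.294071,-0.710239,-0.162858
G,B,DC,O3',O,-0.408908,-0.755293,-0.234959
G,B,DC,C2',C,-0.297280,-0.556688,-0.144428
G,B,DC,C1',C,-0.248412,-0.534964,0.000042
C,A,DC,N1,N,-0.129000,0.450000,0.000000
C,A,DC,C2,C,-0.142139,0.316203,0.000047
C,A,DC,O2,O,-0.253728,0.266853,0.000250
C,A,DC,N3,N,-0.035312,0.236631,-0.000027
C,A,DC,C4,C,0.087102,0.287560,-0.000156
C,A,DC,N4,N,0.196725,0.204438,-0.000173
C,A,DC,C5,C,0.104242,0.427478,0.000200
C,A,DC,C6,C,-0.005261,0.507010,-0.000186
C,A,DC,P,P,0.005982,0.924673,-0.011510
C,A,DC,OP1,O,-0.010293,1.048508,-0.090863
C,A,DC,OP2,O,0.013631,0.798017,-0.110558
C,A,DC,O5',O,-0.119510,0.907712,0.087824
C,A,DC,C5',C,-0.236322,0.900446,0.005984
C,A,DC,C4',C,-0.297348,0.760552,0.016350
C,A,DC,O4',O,-0.216461,0.663919,-0.054591
C,A,DC,C3',C,-0.294071,0.710239,0.162858
C,A,DC,O3',O,-0.408908,0.755293,0.234959
C,A,DC,C2',C,-0.297280,0.556688,0.144428
C,A,DC,C1',C,-0.248412,0.534964,-0.000042
C,B,DG,N9,N,-0.129000,-0.450000,0.000000
C,B,DG,C8,C,0.000469,-0.492906,-0.000026
C,B,DG,N7,N,0.080921,-0.390585,0.000082
C,B,DG,C5,C,0.008068,-0.276293,0.000179
C,B,DG,C6,C,0.040694,-0.138653,0.000309
C,B,DG,O6,O,0.156960,-0.102072,0.000366
C,B,DG,N1,N,-0.060206,-0.048861,-0.000356
C,B,DG,C2,C,-0.189773,-0.090858,0.000189
C,B,DG,N2,N,-0.290146,0.002649,0.000290
C,B,DG,N3,N,-0.221383,-0.218410,0.000199
C,B,DG,C4,C,-0.126976,-0.313201,0.000005
C,B,DG,P,P,0.005982,-0.924673,0.011510
C,B,DG,OP1,O,-0.010293,-1.048508,0.090863
C,B,DG,OP2,O,0.013631,-0.798017,0.110558
C,B,DG,O5',O,-0.119510,-0.907712,-0.087824
C,B,DG,C5',C,-0.236322,-0.900446,-0.005984
C,B,DG,C4',C,-0.297348,-0.760552,-0.016350
C,B,DG,O4',O,-0.216461,-0.663919,0.054591
C,B,DG,C3',C,-0.294071,-0.710239,-0.162858
C,B,DG,O3',O,-0.408908,-0.755293,-0.234959
C,B,DG,C2',C,-0.297280,-0.556688,-0.144428
C,B,DG,C1',C,-0.248412,-0.534964,0.000042
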