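residue,Plr,Chrg,Hydpthy,stablty,ss-stability,vanderWaal,chargetransf,chargedonar,averhydrophocitiy,coilConformation,IsoElectric,Balaban index,RofGyr,ShapeIndex,EIIP
ALA,8.1,0.0,1.8,2.5,0.00,1.00,0,0,0.62,0.82,6.00,2.5395,0.77,0.52,0.0373
ARG,10.5,1.0,-4.5,2.1,0.21,6.13,0,0,-2.53,0.90,10.76,3.0144,2.38,1.45,0.0959
ASN,11.6,0.0,-3.5,0.1,0.65,2.95,0,0,-0.78,1.33,5.41,3.0988,1.45,0.76,0.0036
ASP,13.0,-1.0,-3.5,0.2,0.69,2.78,1,0,-0.90,1.24,2.77,3.0988,1.43,0.76,0.1263
CYS,5.5,0.0,2.5,5.9,0.68,2.43,0,1,0.29,1.07,5.07,2.7542,1.22,0.83,0.0829
GLN,10.5,0.0,-3.5,0.4,0.39,3.95,0,0,-0.85,0.93,5.65,3.0608,1.75,0.99,0.0761
GLU,12.3,-1.0,-3.5,0.1,0.40,3.78,1,0,-0.74,0.99,3.22,3.0608,1.77,0.99,0.0058
GLY,9.0,0.0,-0.4,0.0,1.00,0.00,0,0,0.48,1.42,5.97,1.9747,0.58,0.00,0.0050
HIS,10.4,0.1,-3.2,2.2,0.61,4.66,1,1,-0.40,0.95,7.59,2.1085,1.78,1.07,0.0242
ILE,5.2,0.0,4.5,7.5,0.41,4.00,0,0,1.38,0.78,6.02,3.2925,1.56,1.02,0.0000
LEU,4.9,0.0,3.8,6.9,0.21,4.00,0,0,1.06,0.80,5.98,3.0988,1.54,0.98,0.0000
LYS,11.3,1.0,-3.9,2.0,0.26,4.77,0,0,-1.50,0.99,9.74,2.8766,2.08,1.15,0.0371
MET,5.7,0.0,1.9,5.4,0.24,4.43,0,1,0.64,0.83,5.74,2.8621,1.80,1.10,0.0823
PHE,5.2,0.0,2.8,8.0,0.54,5.89,1,0,1.19,0.91,5.48,2.1325,1.90,1.19,0.0946
PRO,8.0,0.0,-1.6,3.2,3.16,2.72,0,0,0.12,1.49,6.30,2.1400,1.25,0.64,0.0198
SER,9.2,0.0,-0.8,0.4,0.50,1.60,0,0,-0.18,1.28,5.68,2.7542,1.08,0.53,0.0829
THR,8.6,0.0,-0.7,2.1,0.66,2.60,0,0,-0.05,1.09,5.60,3.1442,1.24,0.70,0.0941
TRP,5.4,0.0,-0.9,9.4,0.49,8.08,1,1,0.81,0.94,5.89,1.8713,2.21,1.46,0.0548
TYR,6.2,0.0,-1.3,5.1,0.53,6.47,1,1,0.26,1.05,5.66,2.1681,2.13,1.25,0.0516
VAL,5.9,0.0,4.2,5.0,0.61,3.00,0,0,1.08,0.75,5.96,3.1442,1.29,0.76,0.0057
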