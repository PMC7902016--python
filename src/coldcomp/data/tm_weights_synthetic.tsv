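# synthetic dipeptide Tm-weight table (seeded stand-in; 25% negative, 25% low)
# low_threshold: 0.5
dipeptide	weight
AA	-1.43211
AC	2.18826
AD	-1.60205
AE	0.120414
AF	1.10917
AG	0.518286
AH	1.00495
AI	1.20153
AK	-0.677037
AL	1.96611
AM	2.81175
AN	2.38833
AP	0.0211753
AQ	2.81865
AR	1.82386
AS	0.712029
AT	1.51985
AV	2.66364
AW	1.48143
AY	0.4396
CA	0.526819
CC	0.762449
CD	2.37991
CE	2.71639
CF	-0.941712
CG	0.473012
CH	-2.13553
CI	0.41899
CK	2.77388
CL	0.354952
CM	0.22928
CN	2.19322
CP	0.645271
CQ	-1.90082
CR	1.98803
CS	1.74229
CT	2.1336
CV	2.98866
CW	0.0965207
CY	0.979008
DA	0.202017
DC	1.55095
DD	2.28315
DE	1.37008
DF	-1.84473
DG	-0.597348
DH	-1.99909
DI	0.463898
DK	2.09397
DL	0.667917
DM	-1.3918
DN	-0.16192
DP	2.63004
DQ	-1.3937
DR	0.326217
DS	-2.73687
DT	0.459221
DV	1.49235
DW	-2.58778
DY	1.73322
EA	2.35673
EC	-0.417844
ED	0.393716
EE	0.621746
EF	-2.1884
EG	1.36623
EH	1.72549
EI	0.354789
EK	-1.62436
EL	2.96385
EM	0.282886
EN	2.44336
EP	-1.45733
EQ	0.448517
ER	2.50515
ES	0.213952
ET	1.08634
EV	-2.23985
EW	2.95451
EY	0.952317
FA	-1.02641
FC	2.42157
FD	-0.84672
FE	-1.74418
FF	0.0458605
FG	1.19506
FH	-1.85004
FI	1.60022
FK	2.64137
FL	0.490102
FM	2.90803
FN	0.274572
FP	1.73535
FQ	2.12287
FR	2.60897
FS	1.28613
FT	-1.21895
FV	1.24846
FW	0.305772
FY	0.602367
GA	-0.192181
GC	-0.586825
GD	0.544172
GE	2.30174
GF	0.152352
GG	2.73909
GH	1.35148
GI	-1.52354
GK	0.0865639
GL	2.2941
GM	2.99395
GN	2.92454
GP	1.62061
GQ	1.31336
GR	2.05089
GS	0.499552
GT	2.55646
GV	1.88865
GW	0.400741
GY	0.0272502
HA	0.799181
HC	1.34614
HD	2.4343
HE	2.40358
HF	0.418448
HG	2.94479
HH	0.112796
HI	0.34906
HK	1.84882
HL	0.574018
HM	1.70643
HN	-1.74933
HP	0.025829
HQ	-0.915606
HR	0.308154
HS	0.205905
HT	1.10343
HV	2.51858
HW	-1.56189
HY	2.08635
IA	0.302963
IC	2.35579
ID	2.13526
IE	-0.652128
IF	-2.96309
IG	0.15852
IH	-2.6408
II	-0.153427
IK	0.386054
IL	0.237066
IM	-2.09422
IN	0.909378
IP	-0.986306
IQ	0.700123
IR	-2.20061
IS	1.41652
IT	0.0596088
IV	1.43176
IW	1.75908
IY	1.02264
KA	1.24736
KC	2.59076
KD	1.2774
KE	1.21135
KF	-0.206292
KG	0.204392
KH	-1.08878
KI	2.34858
KK	0.442073
KL	0.215709
KM	1.69376
KN	0.332842
KP	0.323974
KQ	0.85399
KR	-0.659096
KS	1.6332
KT	-1.28271
KV	1.52894
KW	0.390647
KY	-0.0401064
LA	0.324617
LC	0.313006
LD	1.41345
LE	0.0725651
LF	0.254176
LG	0.317315
LH	0.63892
LI	2.37496
LK	0.562058
LL	1.62052
LM	2.99686
LN	-0.708231
LP	-1.15686
LQ	0.100891
LR	1.97686
LS	2.2522
LT	-1.67306
LV	-1.30515
LW	0.490014
LY	2.45501
MA	-2.39279
MC	-0.602267
MD	2.76776
ME	-1.89746
MF	0.286229
MG	0.876682
MH	2.33103
MI	2.59767
MK	0.51125
ML	2.62569
MM	0.368353
MN	0.400482
MP	2.63195
MQ	0.0776065
MR	2.89607
MS	0.367311
MT	1.88992
MV	0.39204
MW	1.49638
MY	0.0742195
NA	1.99619
NC	1.88276
ND	0.0917666
NE	0.773206
NF	2.48421
NG	0.158107
NH	0.351001
NI	2.6112
NK	2.43026
NL	-2.64869
NM	-2.11392
NN	0.180329
NP	-1.6116
NQ	2.56793
NR	0.328135
NS	1.08213
NT	0.914767
NV	2.77266
NW	-2.01492
NY	1.80069
PA	1.93718
PC	0.150671
PD	-1.68629
PE	0.00271492
PF	-1.86161
PG	-0.146417
PH	-1.20122
PI	-0.523802
PK	-1.34102
PL	-1.1515
PM	0.119276
PN	2.17551
PP	0.0180814
PQ	-2.58069
PR	1.81272
PS	0.884032
PT	0.25637
PV	0.372594
PW	-1.23523
PY	0.611623
QA	-2.30229
QC	2.9758
QD	0.289009
QE	2.60498
QF	-0.250957
QG	0.0715109
QH	2.07708
QI	1.09415
QK	-0.822854
QL	-0.12336
QM	-0.427284
QN	-1.04224
QP	0.968984
QQ	2.40726
QR	2.667
QS	1.85214
QT	1.33533
QV	1.22057
QW	2.08442
QY	1.18706
RA	2.26352
RC	-1.87092
RD	2.10222
RE	-0.304901
RF	1.28473
RG	-2.71485
RH	1.48092
RI	1.24091
RK	0.294153
RL	1.4696
RM	2.17903
RN	0.028616
RP	2.59346
RQ	-1.90742
RR	0.680148
RS	-2.64456
RT	2.64531
RV	2.50218
RW	-0.191619
RY	-0.810944
SA	0.842053
SC	2.75832
SD	-2.59634
SE	1.08774
SF	0.139038
SG	0.315006
SH	2.21916
SI	-0.454319
SK	1.26884
SL	0.622409
SM	-2.05668
SN	0.498517
SP	0.305494
SQ	2.05474
SR	2.78825
SS	2.25758
ST	1.35482
SV	1.9758
SW	0.237084
SY	-0.191581
TA	2.74249
TC	0.0452204
TD	-2.55665
TE	1.67332
TF	1.66243
TG	1.78657
TH	0.135379
TI	0.0532098
TK	1.76198
TL	0.0624618
TM	0.455319
TN	0.0552942
TP	1.58445
TQ	0.835917
TR	0.710288
TS	0.932486
TT	-0.4484
TV	1.74704
TW	-2.63424
TY	0.318204
VA	1.43065
VC	0.592427
VD	1.23015
VE	2.0021
VF	-0.942771
VG	0.0144998
VH	-1.08131
VI	2.49968
VK	0.424704
VL	-1.22977
VM	2.79334
VN	1.50339
VP	1.96781
VQ	0.536707
VR	2.71601
VS	0.141954
VT	-2.48613
VV	-2.71471
VW	-0.795321
VY	1.72425
WA	2.80264
WC	1.4123
WD	-2.10937
WE	0.0991021
WF	2.33438
WG	0.0180299
WH	2.89802
WI	1.34714
WK	0.388384
WL	0.0200756
WM	0.325063
WN	-1.40183
WP	-1.55727
WQ	2.63336
WR	-2.74652
WS	0.2092
WT	0.0670473
WV	0.78526
WW	-2.01751
WY	0.809674
YA	-0.712404
YC	0.349888
YD	0.789642
YE	-1.10125
YF	0.470297
YG	1.35823
YH	0.943766
YI	0.712048
YK	-0.614656
YL	-1.56637
YM	2.96145
YN	-1.63705
YP	0.286207
YQ	0.425566
YR	1.82853
YS	-2.52717
YT	0.108814
YV	0.252265
YW	-2.60369
YY	2.97283
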