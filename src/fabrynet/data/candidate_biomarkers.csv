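gene_symbol,uniprot,plasma,urine,cv_accuracy,location
CAMK2A,Q9UQM7,True,False,100,NV
CTSS,P25774,True,False,100,N
FOSL1,P15407,True,False,100,N
PPP1CC,P36873,True,False,100,N
ILK,Q13418,True,False,99,NV
CDK1,P06493,True,False,96,N
GNB5,O14775,True,False,96,N
AKT3,Q9Y243,True,False,96,N
LMNA,P02545,True,True,95,NV
MAPK1,P28482,True,True,95,N
KHSRP,Q92945,True,False,93,NV
PTPN13,Q12923,False,True,92,N
GNB3,P16520,True,False,89,N
STK3,Q13188,True,False,88,N
TGFB2,P61812,False,True,88,N
CIITA,P33076,True,False,87,N
ELAVL1,Q15717,True,False,87,N
VIM,P08670,True,False,86,N
NCAM1,P13591,True,True,84,NV
IL18,Q14116,True,True,84,NV
KPNB1,Q14974,True,False,81,NV
GRIN1,Q05586,True,False,80,N
APP,P05067,True,True,78,N
DNMT1,P26358,True,False,78,N
PML,P29590,True,False,76,NV
BRCA1,P38398,True,False,76,NV
TYMS,P04818,True,False,75,NV
SPP1,P10451,True,False,75,N
ANK3,Q12955,True,False,74,N
ETS1,P14921,True,False,73,N
PKN2,Q16513,True,False,72,N
YWHAQ,P27348,True,False,72,N
HIPK2,Q9H2X6,True,False,71,NV
ANK2,Q01484,True,False,71,NV
DCC,P43146,True,False,71,N
B2M,P61769,True,False,71,NV
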