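CC(=O)Oc1ccccc1C(=O)O
CC(=O)Nc1ccc(O)cc1
CC(C)Cc1ccc(C(C)C(=O)O)cc1
CN1CCC[C@H]1c1cccnc1
Cn1cnc2c1c(=O)n(C)c(=O)n2C
CC(N)Cc1ccccc1
NC(=O)c1ccccc1
OC(=O)c1ccccc1O
Oc1ccccc1
Nc1ccccc1
c1ccc2[nH]ccc2c1
C1CNCCN1
C1COCCN1
c1cncnc1
c1ccoc1
c1ccsc1
c1c[nH]cn1
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
CCOC(=O)C1=C(C)NC(C)=C(C1c1ccccc1[N+](=O)[O-])C(=O)OC
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
Clc1ccccc1
CCN(CC)CC
CCOCC
CCOC(=O)c1ccccc1N
CN(C)CCCN1c2ccccc2CCc2ccccc21
NCCc1ccc(O)c(O)c1
NCCc1c[nH]c2ccccc12
OCC(O)C(O)C(O)C(O)CO
CC(=O)NCCc1c[nH]c2ccc(OC)cc12
COc1cc2c(cc1OC)CC(N)C2
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O
CC(C)C(N)C(=O)O
NC(CO)C(=O)O
NC(Cc1ccccc1)C(=O)O
NC(CS)C(=O)O
NC(CCC(=O)O)C(=O)O
CC(O)C(N)C(=O)O
NC(Cc1c[nH]cn1)C(=O)O
NC(Cc1c[nH]c2ccccc12)C(=O)O
OC(=O)CCc1ccccc1
CC(C)(C)c1ccc(O)cc1
COc1ccc(CCN)cc1
CN1CCN(CC1)c1ccccc1
O=C1CCCCC1
O=C1CCCN1
OC1CCCCC1
CC1CCCCC1
CC(=O)c1ccccc1
CC(=O)C(C)(C)C
CCCCCC(=O)O
CCCCCCCC
CC(C)CCCC(C)C
OCCO
OCCN
NCCN
OCC(O)CO
CC(=O)OCC
CC(C)=O
CC#N
CCO
CCN
CCS
CSC
CCCl
CCBr
FC(F)F
ClC(Cl)Cl
Oc1ccc(Cl)cc1
Nc1ccc(S(N)(=O)=O)cc1
CC(=O)Nc1ccc(S(N)(=O)=O)cc1
COc1ccccc1OC
Cc1ccccc1C
Cc1ccc(C)cc1
CCc1ccccc1
c1ccc(-c2ccccc2)cc1
c1ccc(Cc2ccccc2)cc1
c1ccc(Oc2ccccc2)cc1
O=C(c1ccccc1)c1ccccc1
c1ccc(-c2ccncc2)cc1
c1ccc2ccccc2c1
c1ccc2cc3ccccc3cc2c1
C1CCC2CCCCC2C1
C1CCC(CC1)N1CCCCC1
O=S(=O)(O)c1ccccc1
NS(=O)(=O)c1ccccc1
O=[N+]([O-])c1ccccc1
N#Cc1ccccc1
OCc1ccccc1
O=Cc1ccccc1
CN(C)c1ccccc1
CC(=O)N(C)C
CC(C)(C)OC(=O)NCC(=O)O
CC1=CC(=O)CC(C)(C)C1
O=C1OC(=O)c2ccccc21
c1ccc2c(c1)OCO2
C1COC2(CCCCC2)O1
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O
CC(C)(O)CC(=O)O
CC(Cl)C(=O)O
CN1CCCC1=O
O=C1NC(=O)NC(=O)C1
Cc1ncc([N+](=O)[O-])n1CCO
OCC1OC(O)C(O)C(O)C1O
CC(=O)CC(c1ccccc1)c1ccccc1
CN(C)CCOC(c1ccccc1)c1ccccc1
CC(C)(C)NCC(O)COc1cccc2ccccc12
CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21
CC(C)Cc1ccccc1
COC(=O)c1ccccc1
CCOc1ccccc1
CNC(=O)c1ccccc1
OC(c1ccccc1)c1ccccc1
c1ccc(N2CCCCC2)cc1
CC1CC(C)C(=O)C(C)C1
OC1CCC2(C)C(C1)CCC1C2CCC2(C)C1CCC2O
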