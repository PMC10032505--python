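feature,kit,cost
AGEGRP,Routine measurements,0
BMI,Routine measurements,0
DIASTOLICBP,Routine measurements,0
HEIGHTBL,Routine measurements,0
PULSE,Routine measurements,0
SYSTOLICBP,Routine measurements,0
WEIGHTBL,Routine measurements,0
HB,B-PVKT,40
HEMAT,B-PVKT,40
PLT,B-PVKT,40
RBC,B-PVKT,40
WBC,B-PVKT,40
NEU,TKD,50
POT,TKD,50
ALP,P-AFOS,20
ALT,P-Alat,20
AST,P-AsaT,20
CA,P-Ca,20
CREAT,P-Krea,20
LDH,P-LD,20
PSA,P-PSA,100
TBILI,P-Bil,20
TESTO,S-Testo,330
NA,cB-Het-Ion,100
MG,P-Mg,20
PHOS,P-Pi,20
ALB,P-ALB,20
TPRO,S-Prot,20
LYM,B-Lymf,90
CCRC,Pt-GFReEPI,20
GLU,Gluk,20
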