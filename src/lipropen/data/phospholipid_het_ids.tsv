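# Registry of phosphoglyceride HET IDs (PDB chemical-component identifiers).
# Columns: HET_ID, TAIL_START_ATOMS (comma-separated atom names, optional
# override for mimetic/ether lipids whose tail start cannot be inferred from
# an ester carbonyl), NOTES.
HET_ID	TAIL_START_ATOMS	NOTES
2DP
3PE
3PH
3PI
4PT
6PH
6PL
7PH
8PE
9PE
AGA
B7N
CDL
CDN
CN3
CN5
CN6
CPL
DGG
DLP
DPG
DR9
EPH
GP7
HGP
HGX
HHG
HI5
IP9
L1P
L3P
L4P
L9Q
L9R
LAP
LHG
LIO
LOP
LP3
LPC
LPE
LPP
LPS
LPX
MC3
MYY
NKN
NKO
NKP
NKQ
NKR
OPC
OZ2
P0E
P3A
P42
P6L
PA6
PBU
PC1
PC2
PC6
PC7
PC9
PCF
PCK
PCW
PD7
PDK
PEE
PEF
PEH
PEK
PEV
PEW
PFS
PGK
PGM
PGT
PGV
PGW
PIB
PIE
PIF
PII
PIO
PLC
PLD
PLX
POV
PS2
PS6
PSC
PSF
PT5
PTY
PX4
XPX
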