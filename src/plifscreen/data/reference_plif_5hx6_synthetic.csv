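residue_id,bit
GLY64,0
ALA65,0
VAL66,0
LEU67,0
ILE68,0
SER69,0
LEU70,1
MET71,0
PHE72,0
TYR73,0
LYS74,0
VAL75,1
GLU76,0
ASN77,0
LEU78,1
GLY79,0
ALA80,0
VAL81,0
LEU82,0
ILE83,0
SER84,0
THR85,0
MET86,0
PHE87,0
TYR88,0
LYS89,0
ASP90,0
GLU120,0
ASN121,0
HIS122,0
GLY123,0
ALA124,0
VAL125,0
LEU126,0
ILE127,0
SER128,0
LEU129,1
MET130,0
PHE131,0
TYR132,0
LYS133,0
ASP134,0
GLU135,0
ASN136,0
HIS137,0
GLY138,0
ALA139,0
VAL140,0
LEU145,0
ILE146,0
SER147,0
THR148,0
MET149,0
PHE150,0
TYR151,0
LYS152,0
ASP153,0
GLU154,0
ASN155,0
ASP156,1
LEU157,1
ALA158,0
VAL159,0
LEU160,0
ILE161,0
SER162,0
THR163,0
MET164,0
PHE165,0
TYR166,0
LYS167,0
ASP168,0
GLU169,0
ASN170,0
HIS171,0
GLY172,0
ALA173,0
VAL174,0
LEU175,0
ILE176,0
SER177,0
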