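country,continent
US,America
USA,America
CA,America
MX,America
BR,America
AR,America
CL,America
CO,America
PE,America
FR,Europe
DE,Europe
GB,Europe
UK,Europe
IT,Europe
ES,Europe
NL,Europe
BE,Europe
CH,Europe
AT,Europe
SE,Europe
NO,Europe
DK,Europe
FI,Europe
PL,Europe
PT,Europe
IE,Europe
GR,Europe
CZ,Europe
HU,Europe
RO,Europe
RU,Europe
JP,Asia
CN,Asia
KR,Asia
TW,Asia
IN,Asia
TH,Asia
SG,Asia
MY,Asia
PH,Asia
VN,Asia
ID,Asia
IL,Asia
TR,Asia
SA,Asia
AE,Asia
HK,Asia
AU,Oceania
NZ,Oceania
ZA,Africa
EG,Africa
NG,Africa
KE,Africa
MA,Africa
TN,Africa
DZ,Africa
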