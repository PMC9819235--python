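code,name
BEL,Belgium
BRA,Brazil
CAN,Canada
CHL,Chile
COL,Colombia
DNK,Denmark
FRA,France
DEU,Germany
ITA,Italy
JPN,Japan
MEX,Mexico
NLD,Netherlands
ESP,Spain
SWE,Sweden
GBR,United Kingdom
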