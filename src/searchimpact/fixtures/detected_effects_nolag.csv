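country,term,relative_effect
BRA,depression,-1.71
CHL,stress,0.86
COL,apathetic,2.47
COL,sleep,0.19
COL,tension,0.36
FRA,tension,0.17
DEU,panic,-0.43
DEU,sleep,0.12
MEX,depression,0.60
MEX,sleep,0.21
MEX,stress,1.05
MEX,tension,0.53
MEX,well-being,11.22
NLD,worry,-0.50
SWE,worry,-0.47
GBR,tension,0.17
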