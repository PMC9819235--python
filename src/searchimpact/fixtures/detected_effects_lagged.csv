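country,term,relative_effect
ITA,afraid,-0.99
ITA,boredom,-1.00
ITA,depression,-1.01
ITA,fear,-0.99
ITA,sleep,-1.01
ITA,well-being,-1.01
ITA,worry,-1.00
MEX,stress,1.25
MEX,well-being,9.62
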