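term
contentment
divorce
frustration
impairment
irritability
loneliness
nervous
pissed
sadness
scared
suicide
worthless
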