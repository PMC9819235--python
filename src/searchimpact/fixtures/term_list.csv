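term
afraid
apathetic
boredom
contentment
depression
divorce
fear
frustration
impairment
irritability
loneliness
nervous
panic
pissed
sadness
scared
sleep
stress
suicide
tension
well-being
worry
worthless
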