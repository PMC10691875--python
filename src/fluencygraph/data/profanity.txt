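sod
sucker
scum
sleaze
skank
slob
sissy
screwball
stinker
swine
slimeball
scuzzball
sleazebag
smartypants
sadcase
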