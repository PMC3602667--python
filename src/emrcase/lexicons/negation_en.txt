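# English negation keywords
no
not
without
never
denies
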