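# Dutch negation keywords (one lowercase token per line)
geen
niet
zonder
nooit
noch
geenszins
uitgesloten
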