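# Dutch speculation keywords
mogelijk
mogelijke
waarschijnlijk
vermoedelijk
verdacht
verdenking
wellicht
misschien
eventueel
eventuele
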