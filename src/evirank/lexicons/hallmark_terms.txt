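# The six textbook cancer hallmark keywords.
apoptosis
angiogenesis
growth
invasion
metastasis
proliferation
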