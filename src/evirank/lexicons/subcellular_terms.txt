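# Sub-cellular compartment vocabulary for localization post-processing.
cytoplasm
cytoplasmic
nucleus
nuclear
nucleolus
membrane
mitochondria
mitochondrial
cytosol
cytosolic
golgi
endoplasmic reticulum
lysosome
peroxisome
chromatin
perinuclear
extracellular
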