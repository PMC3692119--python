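# General cancer hypernyms/hyponyms (12 terms). Only three are printed in
# the source description (cancer, tumor, carcinoma); the remainder is a
# documented reconstruction of common WordNet cancer hypo/hypernyms and is
# fully overridable by config.
cancer
tumor
tumour
neoplasm
carcinoma
sarcoma
leukemia
lymphoma
melanoma
glioma
malignancy
adenocarcinoma
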