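# demo synonym -> canonical cancer name table (user-replaceable)
prostate cancer	prostate cancer
prostatic carcinoma	prostate cancer
carcinoma of the prostate	prostate cancer
breast cancer	breast cancer
mammary carcinoma	breast cancer
colon cancer	colon cancer
colorectal cancer	colon cancer
brain cancer	brain cancer
glioblastoma	brain cancer
glioma	brain cancer
pancreatic cancer	pancreatic cancer
leukemia	leukemia
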