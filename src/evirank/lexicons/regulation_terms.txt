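# Relational verbs expressing how a gene drives an event.  Deliberately
# excludes bare event nominals ("regulation", "expression") so that the
# feature measures an explicit gene->event relation word, not the event
# trigger itself.
regulates
regulated
modulates
modulated
mediates
mediated
controls
controlled
governs
governed
influences
influenced
affects
affected
targets
targeted
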