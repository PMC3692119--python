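# Cues marking purpose/method statements and negation: to-infinitive
# phrases, troponyms of "study", and negation words.
to determine
to find
to assess
to investigate
to examine
to evaluate
to explore
to elucidate
to study
examine
examined
investigate
investigated
analyze
analyzed
analyse
analysed
survey
surveyed
not
never
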