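# event type <TAB> trigger word constantly irrelevant for that type
Transcription	described
Transcription	derived
Transcription	prescribed
Transcription	transition
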