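no family history of
no history of
negative for
free of
without
denies
denied
not
no
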