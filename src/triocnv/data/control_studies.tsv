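study_id	n_total
grozeva	10259
rees	6316
szatkiewicz	5917
chapman	1290
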