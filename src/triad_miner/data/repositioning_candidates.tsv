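phrase	doc_freq
cognitive behavior therapy	146
massage therapy	30
homeopathic treatment	16
acupuncture treatments	12
hand arm bimanual intensive training	7
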