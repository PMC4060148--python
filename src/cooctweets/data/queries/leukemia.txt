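# leukemia — profile-search variants
leukemia
白血病
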