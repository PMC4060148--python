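# uterine and cervical cancer — profile-search variants
uterine cancer
cervical cancer
子宮がん
子宮頸がん
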