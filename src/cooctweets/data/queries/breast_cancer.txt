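# breast cancer — profile-search variants
breast cancer
乳がん
乳癌
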