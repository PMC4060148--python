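# colon and colorectal cancer — profile-search variants
colon cancer
rectal cancer
colorectal cancer
大腸がん
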