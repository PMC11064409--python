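code,description
F80,Specific developmental disorders of speech and language (synthetic placeholder list)
F82,Specific developmental disorder of motor function
F88,Other disorders of psychological development
F89,Unspecified disorder of psychological development
R62.0,Delayed milestone in childhood
R62.5,Other and unspecified lack of expected physiological development
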