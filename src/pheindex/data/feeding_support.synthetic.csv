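code,description
R63.3,Feeding difficulties (synthetic placeholder list)
P92,Feeding problems of newborn
Z93.1,Gastrostomy status
Z43.1,Encounter for attention to gastrostomy
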