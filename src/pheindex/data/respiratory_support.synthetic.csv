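code,description
Z99.1,Dependence on respirator (synthetic placeholder list)
Z93.0,Tracheostomy status
Z43.0,Encounter for attention to tracheostomy
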