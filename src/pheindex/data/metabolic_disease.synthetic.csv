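code,description
E70,Disorders of aromatic amino-acid metabolism (synthetic placeholder list)
E71,Disorders of branched-chain amino-acid and fatty-acid metabolism
E72,Other disorders of amino-acid metabolism
E74,Other disorders of carbohydrate metabolism
E75,Disorders of sphingolipid metabolism and other lipid storage disorders
E76,Disorders of glycosaminoglycan metabolism
E77,Disorders of glycoprotein metabolism
E88.4,Mitochondrial metabolism disorders
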