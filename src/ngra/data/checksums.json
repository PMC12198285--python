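{
 "table10_disposition.csv": "6316f4dd2c0715b7702ed0cf11445517a0f929dc050476085dbdb86a53b794c1",
 "table1_reference_values.csv": "4d351a50adfc9d1de8cd1f8bf24a560f4da8cff06efeea2ad02be63348122475",
 "table2_chemical_parameters.csv": "cb3cfe745fdebc3de04b1a9c20047b40c62918f95953e6e779dd69255855ebc0",
 "table3_tissue_ac50.csv": "0d7caed1756f8805fbc285b7781c1dd201df422de5b3a864236d7d8629b786a1",
 "table4_gene_ac50.csv": "d74aa3e46639d781ac10ce6e7303bd0856bfdd693cf45ed75633af37a143d06b",
 "table5_tissue_rp.csv": "01e460232591012f0f68d607a09b4fccf98173e3d4191515c5b55949eab49ff4",
 "table6_gene_rp.csv": "01c6408a7414d877ce7c0c55d623a0c50ecb3ddf50166ba4b9bc3fb3865bfad1",
 "table9_noael_cmax.csv": "a0937f91a062c3f4350fbcd6089c6d6f1f0aa8aefe691653772d55d4eb0f3585"
}
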