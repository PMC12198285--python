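category,bifenthrin,cyfluthrin,cypermethrin,deltamethrin,l-cyhalothrin,permethrin
Androgen receptor,0.31,0.39,0.37,0.29,1.00,0.18
Apoptosis,0.01,1.00,0.91,,,
ATP binding,0.82,0.95,1.00,,,
Collagen,1.00,0.02,0.02,,,
Cytochrome,0.05,0.05,0.07,0.83,1.00,0.06
DNA,1.00,0.85,0.47,0.37,0.42,
Epidermal growth factor,1.00,1.00,,,,
Estrogen,0.59,1.00,0.65,0.57,0.64,0.82
Fatty acid,0.09,1.00,,,,
Glucuronidation,0.57,0.92,0.92,1.00,,
Heat shock protein,1.00,0.25,0.34,,,
Immune system receptor,0.52,0.67,0.63,0.68,0.65,1.00
Inflammation,0.07,0.03,1.00,0.04,0.04,0.08
Insulin,1.00,0.69,,,,
Artherosclerosis,1.00,0.97,,,,
Leukemia,1.00,0.44,,,,
Liver,1.00,,,,,
Thrombosis,0.46,0.14,0.72,1.00,0.56,
Neuroreceptor,1.00,0.09,0.03,0.02,,
Nuclear receptor,0.58,0.55,0.62,0.52,1.00,0.50
Plasminogen,0.06,0.14,1.00,,,
Progesterone receptor,0.52,0.27,0.50,0.70,0.39,1.00
Proliferation,0.58,0.10,1.00,0.15,,
Prostaglandin,0.17,0.15,0.16,0.32,1.00,0.18
Protein coding,1.00,,,,,
Protein kinase,0.24,0.13,1.00,,,
Protein phosphatase,1.00,,,,,
Proteolysis,0.58,0.17,1.00,0.48,,
Sulfotransferase,1.00,0.11,,,,
Thyroid hormone receptor,1.00,0.47,0.37,0.24,0.50,0.18
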