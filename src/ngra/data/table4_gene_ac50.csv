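category,bifenthrin,cyfluthrin,cypermethrin,deltamethrin,l-cyhalothrin,permethrin
Androgen receptor,22.54,17.74,18.92,23.60,6.96,38.27
Apoptosis,50.00,0.32,0.35,,,
ATP binding,36.85,32.02,30.34,,,
Collagen,0.10,4.86,5.08,,,
Cytochrome,18.39,19.14,12.58,1.09,0.91,14.75
DNA,18.39,21.71,39.46,49.43,44.04,
Epidermal growth factor,50.00,50.00,,,,
Estrogen,48.33,28.63,43.91,50.00,44.97,34.81
Fatty acid,34.10,2.98,,,,
Glucuronidation,16.10,10.00,10.03,9.20,,
Heat shock protein,17.23,67.64,51.13,,,
Immune system receptor,8.58,6.69,7.08,6.59,6.86,4.47
Inflammation,7.11,16.33,0.52,14.05,13.16,6.41
Insulin,34.39,50.00,,,,
Artherosclerosis,3.85,3.97,,,,
Leukemia,1.99,4.56,,,,
Liver,26.08,,,,,
Thrombosis,10.02,32.19,6.37,4.60,8.25,
Neuroreceptor,0.33,3.66,12.98,17.67,73.41,
Nuclear receptor,12.08,12.89,11.39,13.55,7.04,14.21
Plasminogen,10.43,4.43,0.62,,,
Progesterone receptor,20.35,39.24,21.24,15.21,26.98,10.65
Proliferation,5.12,28.75,2.98,20.00,,
Prostaglandin,4.12,4.55,4.42,2.14,0.69,3.87
Protein coding,9.23,,,,,
Protein kinase,26.55,50.00,6.34,,,
Protein phosphatase,3.45,,,,,
Proteolysis,3.32,11.64,1.93,4.05,,
Sulfotransferase,5.45,50.00,,,,
Thyroid hormone receptor,17.73,38.03,47.33,74.77,35.75,100.00
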