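chemical_id,tissue,c_nom,c_interst,c_intracel,c_free,c_cell,c_mem,extrapolated
bifenthrin,Vascular system,7.14,0.1,0.1,0.00269,302,11000,False
bifenthrin,Immune system,14.7,0.1,0.1,0.00554,621,22600,False
bifenthrin,Brain,3.12,0.06,243.15,0.00118,132,4800,False
bifenthrin,Kidney,30.09,0.07,152.37,0.0113,1270,46200,False
bifenthrin,Liver,29.75,0.07,167.96,0.0112,1260,45700,False
bifenthrin,Skin,5.78,0.04,306.53,0.00218,244,8870,False
cyfluthrin,Vascular system,12.23,0.1,0.1,0.0026,636,25900,True
cyfluthrin,Immune system,41.3,0.1,0.1,0.0088,2150,87600,True
cyfluthrin,Brain,4.6,0.04,296.29,0.00098,239,9750,True
cyfluthrin,Kidney,33.44,0.12,458.76,0.0071,1740,70900,True
cyfluthrin,Liver,22.82,0.13,502.24,0.0048,1190,48400,True
cyfluthrin,Skin,12.42,0.11,129.59,0.0026,646,26400,True
cypermethrin,Vascular system,8.43,0.32,0.32,0.00279,379,14300,False
cypermethrin,Immune system,66.95,0.32,0.32,0.0222,3010,114000,False
cypermethrin,Brain,8.21,0.25,2209.14,0.00272,369,13900,False
cypermethrin,Kidney,33.56,0.14,386.17,0.0111,1510,57000,False
cypermethrin,Liver,26.03,0.14,427.29,0.00862,1170,44200,False
deltamethrin,Vascular system,45.66,0.0023,0.0023,0.016,1980,73100,True
deltamethrin,Immune system,60.38,0.0023,0.0023,0.022,2620,96700,True
deltamethrin,Brain,11.03,0.0011,4.09,0.004,478,17700,True
deltamethrin,Kidney,27.49,0.00097,2.32,0.0099,1190,44000,True
deltamethrin,Liver,15.57,0.00099,2.52,0.0056,675,24900,True
deltamethrin,Lung,0.96,0.00097,3.01,0.00034,41.6,1540,True
l-cyhalothrin,Vascular system,8.25,0.0093,0.0093,0.0048,250,6750,True
l-cyhalothrin,Immune system,44.09,0.0093,0.0093,0.026,1330,36100,True
l-cyhalothrin,Brain,7.6,0.00451,10.96,0.0044,230,6230,True
l-cyhalothrin,Kidney,35.9,0.0055,7.49,0.021,1090,29400,True
l-cyhalothrin,Liver,13.19,0.0056,8.17,0.0077,399,10800,True
l-cyhalothrin,Lung,0.59,0.0055,9.77,0.00034,17.9,483,True
l-cyhalothrin,Skin,1.55,0.0045,19.26,0.0009,46.8,1270,True
permethrin,Vascular system,7.14,0.07,0.07,0.000372,396,16600,False
permethrin,Kidney,33.62,0.03,214.29,0.00175,1860,78200,False
permethrin,Liver,26.84,0.03,236.79,0.0014,1490,62500,False
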