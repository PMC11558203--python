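wavenumber,metabolite,mode,is_reference
681,Methionine,CO2-wagging,0
701,Cholesterol,"Choline group, CH2 rocking",0
719,Phosphatidylcholine (PC)/sphingomyelin,Symmetric stretch vibration of choline group,0
745,Thymine (DNA bases),"Backbone vibrations, deformation of the ring",0
757,Tryptophan,"Symmetric breathing of tryptophan, sigma(ring)",0
788,DNA/RNA,C'-O-P-O-C'3 phosphodiester bonds,0
805,DNA/RNA,C'-O-P-O-C'3 phosphodiester bonds,0
828,Tyrosine,Ring breathing,0
839,Proline,C-C stretching,0
849,Sugars (glucose and glycerol),C-O-C skeletal stretching,0
878,Glutamic acid,"C-O-C ring, C-O-H bending",0
898,Glycine,"C-C stretching, O-C-O stretching",0
940,"Citric acid, succinic acid",nu(OH...O) out of plane wagging vibration of hydrogen bonds,0
956,Myristic acid,C-H bending,0
991,Arginine,C-N stretching,0
1002,Phenylalanine,Symmetric ring breathing,0
1013,Carbohydrates,"C-O-C ring, C-O-H bending",0
1030,Phenylalanine,C-H in-plane bending,0
1060,Lipids,Chain C-C stretching,0
1078,Lipids,Chain C-C stretching,0
1105,Mannose,sigma(CH2) twisting vibrations,0
1126,Glucose,"C-C stretching, C-O stretching, C-O-H in-plane bending",0
1155,Carotenoids,C-C stretching and C-H stretching,0
1173,Saturated fatty acids,C-C stretching (skeletal option),0
1206,Amino acids,NH3 asymmetric rocking,0
1242,Amide III,Asymmetric O-P-O stretching,0
1265,"Unsaturated lipids, fatty acids","=CH deformation, C-H stretching",0
1309,Triglycerides,CH3 CH2 twisting and bending,0
1317,Histidine,CH3/CH2 twisting and wagging,0
1339,Threonine,CH3/CH2 twisting and wagging,0
1448,Lipids and proteins,"CH2 and CH2CH3 bending, scissoring, and deformation",1
1516,Carotenoids,C-C stretching and C=C stretching,0
1551,Tryptophan,"Symmetric breathing, C-C stretching",0
1576,DNA and NADH,Ring breathing modes,0
1585,Phenylalanine,C-C bending,0
1604,Phenylalanine,Ring C-C stretching,0
1615,Tyrosine,C=C stretching,0
1657,"Unsaturated lipids, PC, phosphatidylethanolamine",C=C stretching,0
1670,Amide I,C=O stretching,0
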