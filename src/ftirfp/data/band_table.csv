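center_cm1,mode,assignment,note
3013,=C-H stretching (olefinic),Unsaturated lipid (acyl chain double bonds),
2959,CH3 asymmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2956,CH3 asymmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2953,CH3 asymmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2925,CH2 asymmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2922,CH2 asymmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2919,CH2 asymmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2916,CH2 and CH3 stretching of phospholipids,"Lipid (long chain fatty acids, phospholipids)",
2874,CH3 symmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2871,CH3 symmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2854,CH2 symmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2851,CH2 symmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
2849,CH2 symmetric stretching,"Lipid (long chain fatty acids, phospholipids)",
1747,C=O stretching,"Triacylglycerol, cholesterol esters, glycerophospholipids",
1743,C=O stretching,"Triacylglycerol, cholesterol esters, glycerophospholipids",
1736,C=O stretching,"Triacylglycerol, cholesterol esters, glycerophospholipids",
1696,Amide I,"Amide-I: anti-parallel beta-sheets (peptide, protein)","80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1693,Amide I,"Amide-I: anti-parallel beta-sheets (peptide, protein)","80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1682,Amide I,"Amide-I: anti-parallel beta-sheets (peptide, protein)","80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1662,Amide I,Amide-I: alpha-helices,"80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1651,Amide I,Amide-I: alpha-helices,"80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1648,Amide I,Amide-I: alpha-helices,"80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1639,Amide I,"Amide-I: parallel beta-sheets (peptide, protein)","80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1631,Amide I,"Amide-I: parallel beta-sheets (peptide, protein)","80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1628,Amide I,"Amide-I: parallel beta-sheets (peptide, protein)","80% C=O stretching, 10% N-H bending, 10% C-N stretching"
1554,Amide II,Amide II (proteins),"60% N-H bending, 40% C-N stretching"
1551,Amide II,Amide II (proteins),"60% N-H bending, 40% C-N stretching"
1543,Amide II,Amide II (proteins),"60% N-H bending, 40% C-N stretching"
1537,Amide II,Amide II (proteins),"60% N-H bending, 40% C-N stretching"
1534,Amide II,Amide II (proteins),"60% N-H bending, 40% C-N stretching"
1523,Amide II,Amide II (proteins),"60% N-H bending, 40% C-N stretching"
1515,CH2 bending,"Lipid, protein",
1512,CH2 bending,"Lipid, protein",
1509,CH2 bending,"Lipid, protein",
1172,C-O stretching,"Carbohydrates/glycogen, nucleic acids",
1155,"C-O stretching, C-O-H bending",Carbohydrates,
1152,"C-O stretching, C-O-H bending",Carbohydrates,
1124,Phosphodiester groups of PO2-,RNA,
1121,Phosphodiester groups of PO2-,RNA,
1112,Phosphodiester groups of PO2-,RNA,
1104,PO2- symmetrical stretching,"DNA, RNA, phospholipid, phosphorylated protein",
1084,PO2- symmetrical stretching,"DNA, RNA, phospholipid, phosphorylated protein",
1079,PO2- symmetrical stretching,"DNA, RNA, phospholipid, phosphorylated protein",
1076,PO2- symmetrical stretching,"DNA, RNA, phospholipid, phosphorylated protein",
1053,C-O stretching and C-OH bending,"DNA and RNA, oligosaccharides, polysaccharides (e.g., glucose)",
1047,C-O stretching and C-OH bending,"DNA and RNA, oligosaccharides, polysaccharides (e.g., glucose)",
1042,C-O stretching and C-OH bending,"DNA and RNA, oligosaccharides, polysaccharides (e.g., glucose)",
1025,C-O stretching and C-OH bending,"DNA and RNA, oligosaccharides, polysaccharides (e.g., glucose)",
1022,C-O stretching and C-OH bending,"DNA and RNA, oligosaccharides, polysaccharides (e.g., glucose)",
1013,C-O stretching and C-OH bending,"DNA and RNA, oligosaccharides, polysaccharides (e.g., glucose)",
996,C-O stretching,DNA and RNA ribose,
994,C-O stretching,DNA and RNA ribose,
991,C-O stretching,DNA and RNA ribose,
968,PO3 2- stretching,DNA and RNA ribose,
931,C-N+-C stretching,DNA and RNA ribose-phosphate chain vibration of RNA,
928,C-N+-C stretching,DNA and RNA ribose-phosphate chain vibration of RNA,
926,C-N+-C stretching,DNA and RNA ribose-phosphate chain vibration of RNA,
923,C-N+-C stretching,DNA and RNA ribose-phosphate chain vibration of RNA,
914,C-N+-C stretching,DNA and RNA ribose-phosphate chain vibration of RNA,
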