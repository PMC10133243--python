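code,common_name,scientific_name,diagnosis,site,tumour_type,annotations,bcacc
BITARI,Puff adder,Bitis arietans,Carcinoma,Pancreas,epithelial,336,0.88
CANFAM,Dog,Canis lupus familiaris,Canine transmissible venereal tumour,Intra vaginal,round-cell,629,0.94
CAPHIR,West African pygmy goat,Capra hircus,Lymphoma,Forestomach,round-cell,965,0.70
CRAHEA,Panay cloudrunner,Crateromys heaneyi,Hepatocellular carcinoma,Liver,epithelial,730,0.89
CYACYA,Red-legged honeycreeper,Cyanerpes cyaneus,Sertoli cell tumour,Testis,sex-cord stromal,762,0.86
DASBYR,Kowari,Dasyuroides byrnei,Squamous cell carcinoma,Mouth,epithelial,462,0.74
GALMOH,Mohol bushbaby,Galago moholi,Squamous cell carcinoma,Skin,epithelial,684,0.79
GONOXY,Red-tailed green ratsnake,Gonyosoma oxycephala,Metastatic anaplastic sarcoma,Multiple,mesenchymal,526,0.91
LEMCAT,Ring-tailed lemur,Lemur catta,Haemangiosarcoma,Kidney,mesenchymal,1049,0.79
LEOCHR,Golden-headed lion tamarin,Leontopithecus chrysomelas,Adenoma,Pituitary,epithelial,601,0.94
LEPFAL,Mountain chicken,Leptodactylus fallax,Adenocarcinoma,Celomic cavity,epithelial,740,0.81
MELURS,Sri Lankan sloth bear,Melursus ursinus inornatus,Pheochromocytoma,Adrenal,neuroendocrine,959,0.88
MUSPUT,Domestic ferret,Mustela putorius furo,Sebaceous epithelioma,Skin,epithelial,702,0.88
NASNAS,South American coati,Nasua nasua,Lymphoma,Multiple,round-cell,520,0.57
OSTTET,African dwarf crocodile,Osteolaemus tetraspis tetraspis,Lipoma,Liver,neuroendocrine,1142,0.77
PANTRO,Chimpanzee,Pan troglodytes,Spindle cell tumour,Palate,mesenchymal,866,0.75
SARHAR,Tasmanian devil,Sarcophilus harrisii,Devil facial tumour 1 (DFT1),Hard palate,round-cell,484,0.88
SPHHUM,Humboldt penguin,Spheniscus humboldti,Renal cell adenoma,Kidney,epithelial,452,0.72
SUSBAR,Bearded Pig,Sus barbatus,Adenocarcinoma,Uterus,epithelial,1595,0.80
VARPRA,Emerald Tree monitor,Varanus prasinus,Spindle cell sarcoma,Multiple,mesenchymal,366,0.80
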