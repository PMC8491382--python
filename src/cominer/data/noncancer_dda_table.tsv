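system	partner_id	partner_name	target_id	target_name	support
comention	C538324	3-Hydroxy-3-methylglutaryl-coa lyase deficiency	D008223	Lymphoma	907
comention	D000163	Acquired immunodeficiency syndrome	D008223	Lymphoma	2358
comention	D000163	Acquired immunodeficiency syndrome	D007938	Leukemia	906
comention	D000686	Amyloidosis	D009101	Multiple Myeloma	1108
comention	D000740	Anemia	D007938	Leukemia	992
comention	D001327	Autoimmune diseases	D008223	Lymphoma	1680
comention	D001847	Bone diseases	D009101	Multiple Myeloma	1548
comention	D002869	Chromosome aberrations	D007938	Leukemia	2834
comention	D002869	Chromosome aberrations	D008223	Lymphoma	1161
comention	D007938	Classical lissencephaly and subcortical band heterotopias	D054221	Leukemia	1836
comention	D008223	Epstein-barr virus infections	D020031	Lymphoma	2985
comention	D005334	Fever	D008223	Lymphoma	1878
comention	D005334	Fever	D007938	Leukemia	1184
comention	D008223	Genetic diseases, inborn	D030342	Lymphoma	25278
comention	D007938	Genetic diseases, inborn	D030342	Leukemia	21078
comention	D009101	Genetic diseases, inborn	D030342	Multiple Myeloma	17621
comention	D006086	Graft versus host disease	D007938	Leukemia	1982
comention	D006402	Hematologic diseases	D007938	Leukemia	1751
comention	D008223	HIV infections	D015658	Lymphoma	1939
comention	D007938	Myelodysplastic syndromes	D009190	Leukemia	2943
comention	D009101	Renal insufficiency	D051437	Multiple Myeloma	1356
comention	D007938	Thrombocytopenia	D013921	Leukemia	1012
gene_overlap	C0004364	Autoimmune Diseases	C0024299	Lymphoma	0.24
gene_overlap	C0023418	Myelodysplastic Syndrome	C3463824	Leukemia	0.25
gene_overlap	C0003873	Rheumatoid Arthritis	C0023418	Leukemia	0.26
gene_overlap	C0003873	Rheumatoid Arthritis	C0026764	Multiple Myeloma	0.25
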