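gene_a	direction_a	gene_b	direction_b	annotation
AT3G49960	decreased	POPTR_007G053400v3	increased	Peroxidase activity, response to oxidative stress, heme binding
AT1G70710	decreased	POPTR_010G109200v3	decreased	Catalytic activity, hyrolase activity, carbohydrate metabolic process
AT1G10550	decreased	POPTR_014G115000v3	decreased	Xyloglucan metabolism, hyrolase activity, carbohydrate metabolic process, cell wall biogenesis
AT5G67400	decreased	POPTR_007G053400v3	increased	Peroxidase activity, response to oxidative stress, heme binding, hydrogen peroxide catabolic process
AT5G23210	decreased	POPTR_005G091700v3	decreased	Proteolysis, serine-type carboxypeptidase activity
AT1G67750	decreased	POPTR_008G182200v3	decreased	Pectate lyase activity, metal ion binding
AT2G39530	decreased	POPTR_010G205300v3	increased	iron/sulfur cluster binding
AT5G13140	decreased	POPTR_003G167100v3	decreased	Response to nematode, pectate lyase activity, metal ion binding
AT1G11580	decreased	POPTR_011G025400v3	increased	Enzyme inhibitor activity, pectinesterase activity, cell wall modification, rRNA N-glycosylase activity, aspartyl esterase activity, toxin activity, defense response
AT3G27400	decreased	POPTR_001G339500v3	increased	Response to nematode, pectate lyase activity, metal ion binding
AT4G02330	decreased	POPTR_014G127000v3	increased	Enzyme inhibitor activity, pectinesterase activity, cell wall modification, response to stress, aspartyl esterase activity
AT5G20630	decreased	POPTR_006G142600v3	decreased	Manganese ion binding, nutrient reservoir activity
AT4G26260	increased	POPTR_018G069700v3	decreased	Iron ion binding, inositol oxygenase activity, syncytium formation, L-ascorbic acid biosynthetic pathway
AT2G44990	increased	POPTR_014G056800v3	decreased	Oxidoreductase activity, secondary shoot formation, carotene catabolic process, strigolactone biosynthetic process, xanthophyll catabolic process, metal ion binding
AT1G70710	decreased	POPTR_010G109200v3	decreased	Cellulase activity, cell wall modification, hydrolase activity
AT1G12940	increased	POPTR_015G081500v3	decreased	Transmembrane transport
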