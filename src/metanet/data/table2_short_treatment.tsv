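metabolite	wildtype_mean	wildtype_sd	disease_mean	disease_sd	disease_vs_wildtype_mark	treated_mean	treated_sd	treated_vs_wildtype_mark	treated_vs_disease_mark
3-hydroxybutyrate	0.0350	0.0051	0.0286	0.0060	*	0.0259	0.0073	**	
3-hydroxyisobutyrate	0.0100	0.0014	0.0099	0.0032		0.0089	0.0013	*	
Acetylcarnitine	0.0959	0.0192	0.0837	0.0244		0.1008	0.0133		#
AMP	1.1135	0.1062	1.1232	0.1194		1.1403	0.1011		
Adenosine	0.0660	0.0104	0.0619	0.0074		0.0653	0.0133		
Alanine	0.3125	0.0359	0.3400	0.0302		0.3440	0.0703		
Asparagine	0.0524	0.0068	0.0654	0.0174		0.0543	0.0211		
Aspartate	0.6435	0.1667	0.5741	0.0923		0.5789	0.0840		
Betaine	0.5111	0.2806	0.5490	0.1055		0.6176	0.1144	**	
Choline	0.2811	0.0801	0.1756	0.0735	**	0.1765	0.0870	*	
Citrate	0.1265	0.0408	0.4854	0.1401	***	0.4609	0.1701	***	
Creatine	0.4999	0.1229	0.4079	0.0823		0.3885	0.0582	*	
Dimethylglycine	0.0028	0.0005	0.0042	0.0018	**	0.0047	0.0016	***	
Fumarate	0.0099	0.0020	0.0295	0.0081	***	0.0237	0.0069	***	
Glucose	2.1753	0.5643	2.0502	0.3447		2.3118	0.5020		
Glutamate	2.7534	0.4267	2.5559	0.3078		2.7637	0.3900		
Glutamine	0.5427	0.1246	0.5796	0.0521		0.6186	0.1566		
Glycine	1.2133	0.1741	0.9836	0.1052	**	0.9664	0.1478	**	
Histidine	0.0648	0.0090	0.0531	0.0062	**	0.0560	0.0127		
Hypoxanthine	0.1372	0.0458	0.1017	0.0171	*	0.0964	0.0182	*	
IMP	0.1810	0.0297	0.1916	0.0222		0.2273	0.0793		
Inosine	0.1745	0.0316	0.1371	0.0273	**	0.1391	0.0290	*	
Isoleucine	0.0646	0.0131	0.0583	0.0060		0.0610	0.0067		
Lactate	2.2616	0.3894	1.9047	0.1372	**	1.8542	0.2573	*	
Leucine	0.1317	0.0381	0.1109	0.0093		0.1127	0.0191		
Malate	0.1721	0.0415	0.3224	0.0500	***	0.3053	0.0655	***	
Methionine	0.0816	0.0174	0.0648	0.0095	*	0.0642	0.0129		
Myo-inositol	3.2799	0.1769	3.0676	0.2129		3.1918	0.2917		
NAD	1.1642	0.0920	1.2663	0.1023	*	1.3881	0.2267	*	
Niacinamide	0.0338	0.0117	0.0346	0.0103		0.0326	0.0115		
Phenylalanine	0.0656	0.0091	0.0860	0.0178	*	0.0824	0.0095	**	
Phosphocholine	0.7226	0.0995	0.8771	0.0742	**	0.7839	0.1248		#
Phosphoethanolamine	0.4589	0.0311	0.5518	0.0481	***	0.5124	0.0719	**	
Succinate	0.5333	0.0463	0.5329	0.0433		0.5427	0.0758		
sn-Glycero-3-phosphocholine	12.1109	2.4684	11.3333	1.4083		12.4028	2.1135		
Taurine	5.1472	0.3412	5.1014	0.3288		4.8403	0.4815		
Threonine	0.2178	0.0584	0.2063	0.0386		0.1810	0.0229	*	
Tyrosine	0.1163	0.0197	0.0985	0.0172	*	0.0856	0.0170	**	#
UDP-N-acetylglucosamine	0.1719	0.0436	0.2196	0.0463	**	0.2693	0.0442	***	
UDP-glucose	0.2510	0.0989	0.2780	0.0610		0.3038	0.0503		
UMP	0.1270	0.0238	0.1544	0.0330		0.1657	0.0367	*	
Uracil	0.0459	0.0096	0.0355	0.0064	*	0.0331	0.0054	***	
Uridine	0.1380	0.0216	0.1277	0.0110		0.1374	0.0187		
Valine	0.1012	0.0135	0.0988	0.0089		0.1105	0.0289		
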