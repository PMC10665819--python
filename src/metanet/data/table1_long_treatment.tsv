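metabolite	wildtype_mean	wildtype_sd	disease_mean	disease_sd	disease_vs_wildtype_mark	treated_mean	treated_sd	treated_vs_wildtype_mark	treated_vs_disease_mark
3-hydroxybutyrate	0.0313	0.0117	0.0450	0.0157	*	0.0376	0.0049		
3-hydroxyisobutyrate	0.0120	0.0016	0.0220	0.0046	***	0.0203	0.0027	***	
AMP	1.8373	0.1242	1.1696	0.2230	***	1.1927	0.1879	***	
Acetylcarnitine	0.1444	0.0216	0.1151	0.0178	***	0.1269	0.0154	*	#
Adenosine	0.0984	0.0110	0.0605	0.0139	***	0.0793	0.0292		
Alanine	0.3916	0.0211	0.4532	0.0526	***	0.4526	0.0725	**	
Asparagine	0.0808	0.0200	0.0890	0.0393		0.0951	0.0376		
Aspartate	1.0967	0.2250	0.6587	0.1354	***	0.5924	0.1229	***	
Betaine	0.5928	0.1240	0.5742	0.0651		0.6672	0.0948	**	###
Choline	0.1339	0.0153	0.1349	0.0519		0.1236	0.0381		
Citrate	0.2876	0.0464	1.9247	1.1474	***	1.4265	0.9523	***	
Creatine	0.7697	0.0811	0.4608	0.0651	***	0.5046	0.0611	***	#
Dimethylglycine	0.0054	0.0014	0.0087	0.0018	***	0.0092	0.0026	***	
Fumarate	0.0145	0.0055	0.0411	0.0168	***	0.0402	0.0124	***	
Glucose	3.9058	0.5990	3.5018	0.8243		3.3540	0.7738	*	
Glutamate	4.1411	0.2765	2.8083	0.4563	***	3.4140	0.6663	**	##
Glutamine	1.0684	0.1268	0.7499	0.2287	***	0.7212	0.1368	***	
Glycine	1.6395	0.1659	0.8398	0.1155	***	0.9282	0.1548	***	
Histidine	0.1056	0.0231	0.0906	0.0146		0.0918	0.0239	*	
Hypoxanthine	0.0744	0.0247	0.0730	0.0181		0.0863	0.0210		
IMP	0.1365	0.0283	0.1976	0.0307	***	0.2008	0.0322	***	
Inosine	0.1341	0.0605	0.0827	0.0282	***	0.1103	0.0333		##
Isoleucine	0.0913	0.0119	0.1046	0.0166	*	0.0966	0.0264		#
Lactate	1.9845	0.2344	2.2382	0.3672	*	2.2726	0.2181	**	
Leucine	0.1523	0.0233	0.2160	0.0690	**	0.1831	0.0844		#
Malate	0.3069	0.0639	0.7125	0.2685	***	0.6094	0.2747	***	
Methionine	0.1421	0.0177	0.1634	0.0439		0.1779	0.0631		
Myo-inositol	4.6834	0.3796	3.6619	0.4542	***	3.8244	0.3414	***	
NAD	1.2833	0.2315	0.7863	0.1649	***	0.9617	0.2659	**	#
Niacinamide	0.0414	0.0152	0.0445	0.0105		0.0524	0.0232		
Phenylalanine	0.0617	0.0227	0.1537	0.0645	***	0.1880	0.1293	***	
Phosphocholine	1.0364	0.0583	1.1542	0.1484	**	1.1706	0.1062	**	
Phosphoethanolamine	1.2099	0.0846	1.3772	0.1728	**	1.3223	0.1920		
sn-Glycero-3-phosphocholine	11.0878	0.9611	5.6711	1.4325	***	6.0422	1.3291	***	
Taurine	8.3204	0.3478	6.5938	0.6781	***	6.1229	0.6739	***	
Threonine	0.2044	0.0201	0.2564	0.0990		0.2273	0.0728		
Tyrosine	0.1425	0.0321	0.1963	0.0450	**	0.1679	0.0811		#
UDP-N-acetylglucosamine	0.2480	0.0575	0.2844	0.0606		0.2983	0.0772		
UMP	0.2549	0.0504	0.2948	0.0459	*	0.2340	0.0540		##
Uracil	0.0388	0.0184	0.0357	0.0053	*	0.0381	0.0069		
Uridine	0.1968	0.0524	0.1131	0.0244	***	0.1374	0.0385	***	#
Valine	0.1447	0.0138	0.1658	0.0220	**	0.1507	0.0435	**	
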