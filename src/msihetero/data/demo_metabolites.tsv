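id	name	formula
C00031	D-Glucose	C6H12O6
C00186	L-Lactate	C3H6O3
C00022	Pyruvate	C3H4O3
C00158	Citrate	C6H8O7
C00042	Succinate	C4H6O4
C00122	Fumarate	C4H4O4
C00149	L-Malate	C4H6O5
C00074	Phosphoenolpyruvate	C3H5O6P
C00020	AMP	C10H14N5O7P
C00144	GMP	C10H14N5O8P
C00002	ATP	C10H16N5O13P3
C00008	ADP	C10H15N5O10P2
C00025	L-Glutamate	C5H9NO4
C00064	L-Glutamine	C5H10N2O3
C00041	L-Alanine	C3H7NO2
C00049	L-Aspartate	C4H7NO4
C00037	Glycine	C2H5NO2
C00065	L-Serine	C3H7NO3
C00078	L-Tryptophan	C11H12N2O2
C00082	L-Tyrosine	C9H11NO3
C00106	Uracil	C4H4N2O2
C00147	Adenine	C5H5N5
C00242	Guanine	C5H5N5O
C00262	Hypoxanthine	C5H4N4O
C00294	Inosine	C10H12N4O5
C00249	Palmitate	C16H32O2
C00712	Oleate	C18H34O2
C01595	Linoleate	C18H32O2
C00219	Arachidonate	C20H32O2
C00097	L-Cysteine	C3H7NO2S
C00051	Glutathione	C10H17N3O6S
C00385	Xanthine	C5H4N4O2
C00299	Uridine	C9H12N2O6
C00212	Adenosine	C10H13N5O4
C00105	UMP	C9H13N2O9P
C00181	D-Xylose	C5H10O5
C00095	D-Fructose	C6H12O6
C00089	Sucrose	C12H22O11
C05382	Sedoheptulose-7-phosphate	C7H15O10P
C00117	Ribose-5-phosphate	C5H11O8P
C00085	Fructose-6-phosphate	C6H13O9P
C00668	Glucose-6-phosphate	C6H13O9P
C00026	2-Oxoglutarate	C5H6O5
C00036	Oxaloacetate	C4H4O5
C00073	L-Methionine	C5H11NO2S
C00123	L-Leucine	C6H13NO2
C00183	L-Valine	C5H11NO2
C00079	L-Phenylalanine	C9H11NO2
C00148	L-Proline	C5H9NO2
C00188	L-Threonine	C4H9NO3
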