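glycolysis	carbohydrate catabolism	C00031	C00186	C00022	C00074	C00085	C00668	C00095	C00089
tca_cycle	citric acid cycle	C00158	C00042	C00122	C00149	C00026	C00036	C00022
amino_acid_metabolism	amino acid pool	C00025	C00064	C00041	C00049	C00037	C00065	C00078	C00082	C00097	C00073	C00123	C00183	C00079	C00148	C00188
nucleotide_metabolism	purine and pyrimidine turnover	C00020	C00144	C00002	C00008	C00106	C00147	C00242	C00262	C00294	C00385	C00299	C00212	C00105
lipid_metabolism	fatty acids	C00249	C00712	C01595	C00219
pentose_phosphate	pentose phosphate pathway	C00117	C05382	C00181	C00668
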