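variant_id	gene_id	cell
ss005	g05	GM12878
ss006	g05	GM12878
ss007	g05	GM12878
ss008	g05	GM12878
ss009	g05	GM12878
ss028	g05	GM12878
ss029	g05	GM12878
ss030	g05	GM12878
ss031	g05	GM12878
ss046	g06	GM12878
ss047	g06	GM12878
ss060	g01	CD14
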