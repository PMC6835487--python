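chemont_id	name	parent_id
0000000	Organic compounds
0000012	Lipids and lipid-like molecules	0000000
0000262	Fatty acids and conjugates	0000012
0000258	Steroids and steroid derivatives	0000012
0000259	Prenol lipids	0000012
0001549	Monoterpenoids	0000259
0001550	Sesquiterpenoids	0000259
0001551	Diterpenoids	0000259
0001553	Triterpenoids	0000259
0000178	Benzene and substituted derivatives	0000000
0002565	Benzoic acids	0000178
0001105	Phthalic acid derivates	0000178
0001392	Lignans, neolignans, and related compounds	0000000
0000050	Lactones	0000000
0000261	Phenylpropanoids and polyketides	0000000
0002504	Cinnamic acids	0000261
0000145	Coumarins and derivatives	0000261
0000253	Stilbenes	0000261
0000190	Methoxyphenols	0000000
0000334	Flavonoids	0000261
0001586	Biflavonoids and polyflavonoids	0000334
0001615	Flavones	0000334
0000337	Flavans	0000334
0001111	Flavonoid glycosides	0000334
0001361	Anthocyanins	0000334
0000011	Carbohydrates and carbohydrate conjugates	0000000
0001540	Monosaccharides	0000011
0001542	Disaccharides	0000011
0000198	Oligosaccharides	0000011
0001539	Polysaccharides	0000011
0002105	Glycosyl compounds	0000011
0000279	Alkaloids and derivatives	0000000
0000264	Organic acids and derivatives	0000000
0004176	Amino acids	0000264
0000348	Peptides	0000264
0000289	Nucleotides	0000000
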