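id,name,smiles,group,pct_inh_30uM,ic50_uM,ic50_se_uM,pct_provenance
a1,"5-amidino-2-[4-(N,N-diethylamino)phenyl]-1H-benzimidazole",NC(=N)c1ccc2[nH]c(c3ccc(N(CC)CC)cc3)nc2c1,a,62.9,,,reported
a2,"5-amidino-2-[4-(N,N-diethylamino)-2-hydroxyphenyl]-1H-benzimidazole",NC(=N)c1ccc2[nH]c(c3ccc(N(CC)CC)cc3O)nc2c1,a,100.0,8.44,0.05,reconstructed
a3,5-amidino-2-[benzo[b]thiophen-2-yl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3cc4ccccc4s3)nc2c1,a,60.6,,,reported
a4,"5-amidino-2-[2,2'-bithiophen-5-yl]-1H-benzimidazole",NC(=N)c1ccc2[nH]c(c3ccc(-c4cccs4)s3)nc2c1,a,92.0,8.34,0.22,reconstructed
a5,5-amidino-2-[4-cyanophenyl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3ccc(C#N)cc3)nc2c1,a,67.8,,,reported
a6,5-amidino-2-[4-(trifluoromethyl)phenyl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3ccc(C(F)(F)F)cc3)nc2c1,a,98.0,9.83,0.08,reconstructed
a7,5-amidino-2-[3H-benzimidazol-5-yl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3ccc4nc[nH]c4c3)nc2c1,a,21.6,,,reported
a8,5-amidino-2-[naphthalen-1-yl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3cccc4ccccc34)nc2c1,a,38.7,,,reported
a9,5-amidino-2-[quinolin-2-yl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3ccc4ccccc4n3)nc2c1,a,82.9,,,reported
a10,5-amidino-2-[2-hydroxyphenyl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3ccccc3O)nc2c1,a,24.3,,,reported
a11,"5-amidino-2-[2,4-dihydroxyphenyl]-1H-benzimidazole",NC(=N)c1ccc2[nH]c(c3ccc(O)cc3O)nc2c1,a,14.6,,,reported
a12,5-amidino-2-[2-hydroxy-4-methoxyphenyl]-1H-benzimidazole,NC(=N)c1ccc2[nH]c(c3ccc(OC)cc3O)nc2c1,a,50.8,,,reconstructed
b1,"5-(2-imidazolinyl)-2-[4-(N,N-dimethylamino)phenyl]-1H-benzimidazole",C3(=NCCN3)c1ccc2[nH]c(c3ccc(N(C)C)cc3)nc2c1,b,52.9,,,reported
b2,5-(2-imidazolinyl)-2-[phenanthren-9-yl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3cc4ccccc4c4ccccc34)nc2c1,b,100.0,11.05,0.34,reconstructed
b3,5-(2-imidazolinyl)-2-[benzo[b]thiophen-2-yl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3cc4ccccc4s3)nc2c1,b,59.4,,,reported
b4,"5-(2-imidazolinyl)-2-[2,2'-bithiophen-5-yl]-1H-benzimidazole",C3(=NCCN3)c1ccc2[nH]c(c3ccc(-c4cccs4)s3)nc2c1,b,94.0,4.98,0.04,reconstructed
b5,5-(2-imidazolinyl)-2-[4-cyanophenyl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3ccc(C#N)cc3)nc2c1,b,34.4,,,reported
b6,5-(2-imidazolinyl)-2-[4-(trifluoromethyl)phenyl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3ccc(C(F)(F)F)cc3)nc2c1,b,98.0,8.18,0.09,reconstructed
b7,5-(2-imidazolinyl)-2-[3H-benzimidazol-5-yl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3ccc4nc[nH]c4c3)nc2c1,b,51.5,,,reported
b8,5-(2-imidazolinyl)-2-[naphthalen-1-yl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3cccc4ccccc34)nc2c1,b,29.5,,,reported
b9,5-(2-imidazolinyl)-2-[quinolin-2-yl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3ccc4ccccc4n3)nc2c1,b,73.4,,,reported
b10,5-(2-imidazolinyl)-2-[2-hydroxyphenyl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3ccccc3O)nc2c1,b,42.8,,,reported
b11,"5-(2-imidazolinyl)-2-[2,4-dihydroxyphenyl]-1H-benzimidazole",C3(=NCCN3)c1ccc2[nH]c(c3ccc(O)cc3O)nc2c1,b,41.1,,,reported
b12,5-(2-imidazolinyl)-2-[2-hydroxy-4-methoxyphenyl]-1H-benzimidazole,C3(=NCCN3)c1ccc2[nH]c(c3ccc(OC)cc3O)nc2c1,b,48.6,,,reconstructed
b13,"5-(2-imidazolinyl)-2-[2,3,4-trihydroxyphenyl]-1H-benzimidazole",C3(=NCCN3)c1ccc2[nH]c(c3ccc(O)c(O)c3O)nc2c1,b,99.0,1.03,0.01,reconstructed
c1,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[4-(N,N-dimethylamino)phenyl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc(N(C)C)cc3)nc2c1,c,10.0,,,reconstructed
c2,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[4-(N,N-diethylamino)phenyl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc(N(CC)CC)cc3)nc2c1,c,100.0,13.83,0.45,reported
c3,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[4-(N,N-diethylamino)-2-hydroxyphenyl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc(N(CC)CC)cc3O)nc2c1,c,90.5,19.25,0.73,reconstructed
c4,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[2,2'-bithiophen-5-yl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc(-c4cccs4)s3)nc2c1,c,91.5,13.36,0.07,reconstructed
c5,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[4-cyanophenyl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc(C#N)cc3)nc2c1,c,0.1,,,reported
c6,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[4-(trifluoromethyl)phenyl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc(C(F)(F)F)cc3)nc2c1,c,15.5,,,reported
c7,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[3H-benzimidazol-5-yl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc4nc[nH]c4c3)nc2c1,c,29.8,,,reported
c8,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[phenanthren-9-yl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3cc4ccccc4c4ccccc34)nc2c1,c,51.7,,,reported
c9,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[phenyl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccccc3)nc2c1,c,2.1,,,reported
c10,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[naphthalen-2-yl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3ccc4ccccc4c3)nc2c1,c,8.0,,,reported
c11,"5-(1,4,5,6-tetrahydropyrimidin-2-yl)-2-[benzo[b]thiophen-2-yl]-1H-benzimidazole",C3(=NCCCN3)c1ccc2[nH]c(c3cc4ccccc4s3)nc2c1,c,28.9,,,reported
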