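# Demonstrative reactive-group (REOS-style) and frequent-hitter (PAINS-style)
# SMARTS patterns. One pattern per line: <name><TAB><class><TAB><SMARTS>.
# The set is deliberately small and editable; flagged compounds are reported,
# not auto-rejected.
nitro_aromatic	reactive	[c][N+](=O)[O-]
aldehyde	reactive	[CX3H1](=O)[#6]
acyl_halide	reactive	[CX3](=O)[F,Cl,Br,I]
alkyl_halide	reactive	[CX4][Cl,Br,I]
michael_acceptor	reactive	[CX3]=[CX3][CX3]=[OX1]
epoxide	reactive	C1OC1
isocyanate	reactive	N=C=O
quinone	frequent_hitter	O=C1C=CC(=O)C=C1
catechol	frequent_hitter	c1ccc(O)c(O)c1
rhodanine	frequent_hitter	S1C(=S)NC(=O)C1
ene_rhodanine	frequent_hitter	S1C(=S)NC(=O)C1=C
hydroxyphenyl_hydrazone	frequent_hitter	c1cc(O)ccc1C=NN
azo	frequent_hitter	[#6]N=N[#6]
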