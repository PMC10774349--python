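index	sequence	domain	phylum	class	order	family	genus	species	direction	PRJNA578223	PRJNA589343
1		Bacteria	Proteobacteria	Gammaproteobacteria	Enterobacterales	Enterobacteriaceae	NA	NA	ASD increased	Yes	Yes
2		Bacteria	Actinobacteria	Actinobacteria	Bifidobacteriales	Bifidobacteriaceae	Bifidobacterium	NA	ASD decreased	Yes	Yes
3		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	Lachnospira	NA	ASD increased	Yes	Yes
4		Bacteria	Bacteroidota	Bacteroidia	Bacteroidales	Tannerellaceae	Parabacteroides	NA	ASD increased	Yes	No
5		Bacteria	Bacteroidota	Bacteroidia	Bacteroidales	Prevotellaceae	NA	NA	ASD increased	No	Yes
6		Bacteria	Firmicutes	Clostridia	Eubacteriales	Oscillospiraceae	Oscillospira	NA	ASD increased	No	Yes
7		Bacteria	Firmicutes	Clostridia	Eubacteriales	Clostridiaceae	Sarcina	NA	ASD increased	Yes	Yes
8		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	NA	NA	ASD increased	Yes	Yes
9		Bacteria	Firmicutes	Clostridia	Eubacteriales	Clostridiaceae	NA	NA	ASD increased	Yes	Yes
10		Bacteria	Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelatoclostridiaceae	NA	NA	ASD decreased	Yes	Yes
11		Bacteria	Firmicutes	Clostridia	Eubacteriales	Clostridiaceae	Clostridium	NA	ASD increased	Yes	Yes
12		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	Anaerosporobacter	NA	ASD increased	Yes	Yes
13		Bacteria	Actinobacteria	Coriobacteriia	Coriobacteriales	Coriobacteriaceae	Collinsella	NA	ASD decreased	Yes	Yes
14		Bacteria	Firmicutes	Clostridia	Eubacteriales	Clostridiaceae	Butyricicoccus	NA	ASD decreased	Yes	Yes
15		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	Lachnospira	Eubacterium eligens	ASD decreased	Yes	Yes
16		Bacteria	Firmicutes	Erysipelotrichia	Erysipelotrichales	Erysipelatoclostridiaceae	Erysipelatoclostridium	NA	ASD decreased	Yes	Yes
17		Bacteria	Proteobacteria	Gammaproteobacteria	Enterobacterales	Enterobacteriaceae	NA	NA	ASD increased	Yes	Yes
18		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	NA	NA	ASD increased	No	No
19		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	Lachnospiraceae UCG-004	NA	ASD decreased	Yes	Yes
20		Bacteria	Firmicutes	Clostridia	Eubacteriales	Clostridiaceae	Clostridium	NA	ASD increased	Yes	Yes
21		NA	NA	NA	NA	NA	NA	NA	ASD increased	Yes	Yes
22		Bacteria	Firmicutes	Tissierellia	Tissierellales	Peptoniphilaceae	Murdochiella	NA	ASD decreased	No	Yes
23		Bacteria	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	NA	NA	ASD increased	No	No
24		Bacteria	Proteobacteria	Gammaproteobacteria	Enterobacterales	Enterobacteriaceae	NA	NA	ASD decreased	Yes	Yes
25		Bacteria	NA	NA	NA	NA	NA	NA	ASD increased	No	No
26		Bacteria	Firmicutes	Clostridia	Eubacteriales	Clostridiaceae	Clostridium	NA	ASD decreased	Yes	Yes
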