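strain_id	family	accession	butyrate	propionate	gaba	indole	siderophore	bile_acid	antimicrobial
Bacteroides xylanisolvens GGCC_0124	Bacteroidaceae	JABFCE000000000		+	+	+		7-alpha-hydroxysteroid dehydrogenase;choloylglycine hydrolase;3-oxo-5-alpha-steroid-4-dehydrogenase	
Clostridium butyricum GGCC_0151	Clostridiaceae	JABFCF000000000	+					7-alpha-hydroxysteroid dehydrogenase;choloylglycine hydrolase;taurine uptake	
Clostridium scindens GGCC_0168	Lachnospiraceae	JABFCG000000000						7-alpha-dehydratase;3-alpha-hydroxy bile acid-CoA-ester-3 dehydrogenase;7-alpha-hydroxysteroid dehydrogenase;choloylglycine hydrolase;L-carnitine hydratase	lactococcin 972-like bacteriocin synthesis
Intestinimonas butyriciproducens GGCC_0179	Ruminococcaceae	JABFHK000000000	+					L-carnitine hydratase	linocin M18-like bacteriocin synthesis
Eubacterium callanderi GGCC_0197	Eubacteriaceae	JABFAG000000000	+	+				7-alpha-hydroxysteroid dehydrogenase;choloylglycine hydrolase;sodium-bile acid symporter	linocin M18-like bacteriocin synthesis
Extibacter sp. GGCC_0201	Lachnospiraceae	JABFCH000000000						7-alpha-dehydratase;7-beta-dehydratase;L-carnitine hydratase	lantipeptide synthesis
Akkermansia sp. GGCC_0220	Akkermansiaceae	JABFCI000000000		+	+	+		sodium-bile acid symporter	
Clostridium symbiosum GGCC_0272	Lachnospiraceae	JABFCJ000000000	+				yersiniabactin synthesis	7-alpha-hydroxysteroid dehydrogenase;choloylglycine hydrolase;L-carnitine hydratase;taurine uptake	
Bacteroides uniformis GGCC_0301	Bacteroidaceae	JABFCK000000000		+	+	+		choloylglycine hydrolase;3-oxo-5-alpha-steroid-4-dehydrogenase;sodium-bile acid symporter	
Bitterella massiliensis GGCC_0305	Lachnospiraceae	JABFCL000000000	+					3-alpha-hydroxysteroid dehydrogenase;3-beta-hydroxysteroid dehydrogenase	
Barnesiella sp. GGCC_0306	Porphyromonadaceae S24-7	JABFCM000000000		+		+		choloylglycine hydrolase;3-oxo-5-alpha-steroid-4-dehydrogenase	
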