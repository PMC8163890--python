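strain_id	family	accession	butyrate	propionate	gaba	indole	siderophore	bile_acid	antimicrobial
Megamonas funiformis DSM19343	Selenomonadaceae	742816.3		+			ferrichrome uptake;enterobactin uptake		
Megamonas hypermegale DSM1672	Selenomonadaceae	1122216.3		+			ferrichrome uptake		
Acidaminococcus intestini DSM21505	Acidaminococcaceae	1120921.3		+					
Bacteroides massiliensis DSM17679	Bacteroidaceae	1121098.3		+			heterologous siderophore uptake		
Bacteroides stercoris ATCC43183 / DSM19555	Bacteroidaceae	449673.7		+		+	heterologous siderophore uptake;enterobactin uptake		
Barnesiella intestinihominis DSM21032	Porphyromonadaceae	742726.3		+			heterologous siderophore uptake;aerobactin uptake		
Faecalibacterium prausnitzii DSM17677	Ruminococcaceae	411483.3	+				heterologous siderophore uptake		bacteriocin synthesis
Subdoligranulum variabile DSM15176	Ruminococcaceae	411471.5	+						bacteriocin synthesis
Anaerostipes caccae DSM14662	Lachnospiraceae	411490.6	+				heterologous siderophore uptake;ferrichrome uptake;yersiniabactin synthesis	7-alpha-hydroxysteroid dehydrogenase	bacteriocin synthesis
Anaerostipes hadrus DSM3319 / ATCC 29173	Lachnospiraceae	649757.3	+	+					
Clostridium symbiosum ATCC14940	Lachnospiraceae	411472.5	+					3-alpha-hydroxysteroid dehydrogenase;7-alpha-hydroxysteroid dehydrogenase	
Akkermansia muciniphila ATCC BAA-835	Akkermansiaceae	349741.6		+		+	heterologous siderophore uptake		
Clostridium scindens ATCC35704	Lachnospiraceae	411468.9						7-alpha-dehydratase	bacteriocin synthesis
Clostridium bolteae ATCC BAA-613	Lachnospiraceae	411902.9					siderophore synthesis	3-alpha-hydroxysteroid dehydrogenase;7-alpha-hydroxysteroid dehydrogenase	bacteriocin synthesis
Blautia producta DSM2950	Lachnospiraceae	1121114.4		+			heterologous siderophore uptake;ferrichrome uptake		
Blautia hydrogenotrophica DSM10507	Lachnospiraceae	476272.21						7-alpha-dehydratase;3-beta-hydroxysteroid dehydrogenase	bacteriocin synthesis
Marvinbryantia formatexigens DSM14469	Lachnospiraceae	478749.5					heterologous siderophore uptake;ferrichrome uptake		
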