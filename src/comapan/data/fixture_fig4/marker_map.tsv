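trait	markers
nitrate_reduction	narG,narH,narI
urea_hydrolysis	ureC
testosterone_utilization	tesB,tesD
adipate_utilization	pcaI,pcaJ
malate_utilization	mdh
gluconate_utilization	gntK
acetate_utilization	acs
lactate_utilization	lldD
4HBA_utilization	pobA,ligA,ligB
citrate_utilization	gltA,citT
decanoate_utilization	fadD
penicillin_resistance	ampC
prostaphlin_resistance	blaOXA
ampicillin_resistance	ampR
copper_resistance	cutE,copA
zinc_resistance	zntA,czcA
tryptophan_hydrolysis	tnaA
glucoside_hydrolysis	bglB
gelatin_hydrolysis	gelE
galactoside_hydrolysis	lacZ
glucose_acidification	glf
glucose_utilization	glk
arabinose_utilization	araA
mannose_utilization	manA
mannitol_utilization	mtlD
NAG_utilization	nagK
maltose_utilization	malZ
tetracycline_resistance	tetA
mercury_resistance	merA,merR
arginine_dihydrolase	arcA
kanamycin_resistance	aphA
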