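trait	S44	JL14	JL40	JC8	JC9	JC12	JC13	DS1	D4	DF1	DF2
nitrate_reduction	+	+	+	+	+	+	+	+	+	+	+
urea_hydrolysis	+	+	+	+	+	+	+	+	+	+	+
testosterone_utilization	+	+	+	+	+	+	+	+	+	+	+
adipate_utilization	+	+	+	+	+	+	+	+	+	+	+
malate_utilization	+	+	+	+	+	+	+	+	+	+	+
gluconate_utilization	+	+	+	+	+	+	+	+	+	+	+
acetate_utilization	+	+	+	+	+	+	+	+	+	+	+
lactate_utilization	+	+	+	+	+	+	+	+	+	+	+
4HBA_utilization	+	+	+	+	+	+	+	+	+	+	+
citrate_utilization	+	+	+	+	+	+	+	+	+	+	+
decanoate_utilization	+	+	+	+	+	+	+	+	+	+	+
penicillin_resistance	+	+	+	+	+	+	+	+	+	+	+
prostaphlin_resistance	+	+	+	+	+	+	+	+	+	+	+
ampicillin_resistance	+	+	+	+	+	+	+	+	+	+	+
copper_resistance	+	+	+	+	+	+	+	+	+	+	+
zinc_resistance	+	+	+	+	+	+	+	+	+	+	+
tryptophan_hydrolysis	-	-	-	-	-	-	-	-	-	-	-
glucoside_hydrolysis	-	-	-	-	-	-	-	-	-	-	-
gelatin_hydrolysis	-	-	-	-	-	-	-	-	-	-	-
galactoside_hydrolysis	-	-	-	-	-	-	-	-	-	-	-
glucose_acidification	-	-	-	-	-	-	-	-	-	-	-
glucose_utilization	-	-	-	-	-	-	-	-	-	-	-
arabinose_utilization	-	-	-	-	-	-	-	-	-	-	-
mannose_utilization	-	-	-	-	-	-	-	-	-	-	-
mannitol_utilization	-	-	-	-	-	-	-	-	-	-	-
NAG_utilization	-	-	-	-	-	-	-	-	-	-	-
maltose_utilization	-	-	-	-	-	-	-	-	-	-	-
tetracycline_resistance	-	-	-	-	-	-	-	-	-	-	-
mercury_resistance	+	+	+	-	-	-	-	+	-	+	+
arginine_dihydrolase	-	-	-	-	+	-	-	-	-	-	-
kanamycin_resistance	-	-	-	-	-	-	-	+	-	-	-
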