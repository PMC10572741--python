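# Flavin-based extracellular electron transfer gene catalog.
# Canonical labels follow the Listeria monocytogenes EET operon nomenclature.
# name_patterns / product_patterns: case-insensitive regexes; ';;' separates
# alternative patterns within a cell. Name matches take precedence over
# product matches; among equal kinds the longer (more specific) pattern wins.
# The ndh2 product patterns deliberately require type-II / ndh context so
# that complex-I-style "NADH dehydrogenase" annotations do not match.
label	role	name_patterns	product_patterns
ecfA	FAD transport	^ecfa$;;^ecfa1$	energy-coupling factor.*ATP-binding protein EcfA1?$;;ECF transporter ATPase 1
ecfA'	FAD transport	^ecfa'$;;^ecfa2$	energy-coupling factor.*ATP-binding protein (EcfA'|EcfA2);;ECF transporter ATPase 2
fmnA	FAD transport	^fmna$	FAD transporter;;flavin.{0,20}transporter FmnA
apbE/fmnB	FAD transport	^apbe$;;^fmnb$	FAD:protein FMN transferase;;flavin transferase
eetA	electron transfer	^eeta$	extracellular electron transfer.*EetA;;EetA family;;DUF3324
eetB	electron transfer	^eetb$	extracellular electron transfer.*EetB;;EetB family;;DUF3318
ndh2	electron transfer	^ndh2$;;^ndh-2$	type ?II NADH.{0,20}(dehydrogenase|oxidoreductase);;NADH dehydrogenase.{0,20}ndh-?2;;ndh-?2-?like
pplA	electron transfer	^ppla$	peptide pheromone.{0,30}lipoprotein;;FMN-binding.{0,20}lipoprotein;;FMNylated
frdA-like	electron transfer	^frda$	fumarate reductase.*flavoprotein
dmkA	DMK synthesis	^dmka$;;^mena$	1,4-dihydroxy-2-naphthoate.{0,20}(prenyl|octaprenyl|polyprenyl)transferase;;demethylmenaquinone synthesis protein A
dmkB	DMK synthesis	^dmkb$	DmkB;;demethylmenaquinone.{0,30}(biosynthesis|processing)
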