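id	equation	reversible	atp	nadh	nadph
glc_upt	glc_e -> hexp	0	-1	0	0
xyl_upt	xyl_e -> penp	0	-1	0	0
pfk	hexp -> 2 gap	0	-1	0	0
gapdh	gap -> pga	0	1	1	0
eno	pga -> pep	0	0	0	0
pyk	pep -> pyr	0	1	0	0
pdh	pyr -> accoa + co2	0	0	1	0
ppc	pep + co2 -> oaa	0	0	0	0
cs	oaa + accoa -> icit	0	0	0	0
icd	icit -> akg + co2	0	0	0	1
efe	akg -> eth_e + 3 co2	0	0	0	0
tkt1	2 penp <-> s7p + gap	1	0	0	0
tal	s7p + gap <-> e4p + hexp	1	0	0	0
tkt2	penp + e4p <-> hexp + gap	1	0	0	0
tpi	gap <-> dhap	1	0	0	0
fba	dhap + gap -> fbp	0	0	0	0
fbpase	fbp -> hexp	0	0	0	0
sba	e4p + dhap -> sbp	0	0	0	0
sbpase	sbp -> s7p	0	0	0	0
pgared	pga -> gap	0	-1	0	-1
prk	penp -> rubp	0	-1	0	0
rubisco	rubp + co2 -> 2 pga	0	0	0	0
co2_in	co2_e -> co2	0	0	0	0
co2_out	co2 -> co2_e	0	0	0	0
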