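id	name	carbons	nitrogens	external
glc_e	glucose (medium)	6	0	1
xyl_e	xylose (medium)	5	0	1
co2_e	carbon dioxide (environment)	1	0	1
eth_e	ethylene (off-gas)	2	0	1
hexp	hexose 6-phosphate	6	0	0
gap	glyceraldehyde 3-phosphate	3	0	0
dhap	dihydroxyacetone phosphate	3	0	0
fbp	fructose 1,6-bisphosphate	6	0	0
pga	3-phosphoglycerate	3	0	0
pep	phosphoenolpyruvate	3	0	0
pyr	pyruvate	3	0	0
accoa	acetyl-CoA (acetyl moiety)	2	0	0
oaa	oxaloacetate	4	0	0
icit	isocitrate	6	0	0
akg	2-oxoglutarate	5	0	0
penp	pentose 5-phosphate pool	5	0	0
e4p	erythrose 4-phosphate	4	0	0
s7p	sedoheptulose 7-phosphate	7	0	0
sbp	sedoheptulose 1,7-bisphosphate	7	0	0
rubp	ribulose 1,5-bisphosphate	5	0	0
co2	carbon dioxide (intracellular)	1	0	0
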