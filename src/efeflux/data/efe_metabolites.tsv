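id	name	carbons	nitrogens	external
akg	2-oxoglutarate (alpha-ketoglutarate)	5	0	0
o2	dioxygen	0	0	1
arginine	L-arginine	6	4	0
ethylene	ethylene	2	0	1
succinate	succinate	4	0	1
co2	carbon dioxide	1	0	1
guanidine	guanidine	1	3	1
p5c	L-delta1-pyrroline-5-carboxylate	5	1	1
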