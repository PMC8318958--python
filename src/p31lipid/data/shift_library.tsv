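# p31lipid 31P chemical-shift library, version 1.0
# 324 MHz 31P, CUBO solvent system, referenced to phosphatidylcholine at 0.00 ppm.
lipid_class	ppm_low	ppm_high	provenance	ambiguous
LPA	5.9	6.1	concentration/age/type scans; lecithin and mouse tissues	false
PA	5.2	5.4	concentration/age/type scans; lecithin and mouse tissues	false
LPI	1.55	1.65	concentration/age/type scans; lecithin and mouse tissues	false
PG	1.20	1.28	concentration/age/type scans; downfield PG signal	false
PG	0.95	1.15	adduct panel labels this interval PI; alternate=PI	false
SM	0.80	0.85	concentration/age/type scans; mouse tissues	false
PE	0.57	0.60	busy region 0.45-0.60; alternates=PE-plasmalogen,PS,LPC	true
PE	0.55	0.57	busy region 0.45-0.60; alternates=PE-plasmalogen,PS,LPC	true
PE	0.51	0.55	busy region 0.45-0.60; alternates=PE-plasmalogen,PS,LPC	true
PE	0.48	0.50	busy region 0.45-0.60; alternates=PE-plasmalogen,PS,LPC	true
LPC	0.43	0.46	busy region 0.45-0.60; alternates=PE-plasmalogen,PS	true
UNK1	0.25	0.30	unidentified signal; lecithin	false
UNK2	0.16	0.19	unidentified signal; lecithin	false
PC	0.00	0.00	calibration reference	false
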