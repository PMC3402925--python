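Chromosome	Begin	End	Evolutionary branch
chr1	10382322	10382387	dog
chr1	109923784	109923788	chimp
chr1	143495190	143766399	macaque
chr1	144691208	144707142	primates
chr1	144850157	145574145	chimp
chr1	150079680	150138541	dog
chr3	126855424	127207816	primates
chr3	128287101	128299344	macaque
chr5	102756311	102787215	mouse
chr5	110090786	110287080	rodents
chr5	112304457	112304458	rat
chr22	34277622	34286037	rodents
chr22	37056914	37068605	rat
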