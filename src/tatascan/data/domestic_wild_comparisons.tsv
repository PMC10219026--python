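# Published per-comparison differential-expression counts between domestic
# animals and their wild counterparts (RNA-Seq, 18 comparisons).
domestic	wild	tissue	n_deg	ref
tame rats	aggressive rats	hypothalamus	46	R212
tame rats	aggressive rats	hippocampus	42	R99
tame rats	aggressive rats	midbrain tegmentum	31	R213
tame rats	aggressive rats	periaqueductal gray matter	39	R214
tame rats	aggressive rats	frontal cortex	20	R215
guinea pigs	cavy	frontal cortex	883	R215
domestic rabbits	wild rabbits	frontal cortex	17	R215
domestic rabbits	wild rabbits	parietal-temporal cortex	216	R216
domestic rabbits	wild rabbits	amygdala	118	R216
domestic rabbits	wild rabbits	hypothalamus	43	R216
domestic rabbits	wild rabbits	hippocampus	100	R216
dogs	wolves	blood	450	R217
dogs	wolves	frontal cortex	13	R215
tame foxes	aggressive foxes	pituitary	327	R218
pigs	boars	frontal cortex	30	R215
pigs	boars	frontal cortex	34	R219
pigs	boars	pituitary	22	R220
domestic chicken	wild chicken	pituitary	474	R221
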