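# tatascan default dinucleotide bend-propensity scale, v1 (dimensionless,
# higher = more bendable).  Package-defined ranking following the known
# base-step flexibility hierarchy: pyrimidine-purine steps (TA, CA/TG, CG)
# bend most readily, G/C-only steps are stiffest.
dinucleotide	bend
TA	1.00
CA	0.80
TG	0.80
CG	0.60
AT	0.55
AG	0.45
CT	0.45
GA	0.40
TC	0.40
AA	0.35
TT	0.35
AC	0.30
GT	0.30
CC	0.20
GG	0.20
GC	0.15
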