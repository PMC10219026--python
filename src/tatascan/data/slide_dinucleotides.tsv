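# Unified nearest-neighbour duplex stability, delta-G at 37 C in kcal/mol
# (SantaLucia 1998 unified parameters).  Used as the dinucleotide
# composition statistic behind the sliding (nonspecific binding) term.
dinucleotide	delta_g
AA	-1.00
AT	-0.88
TA	-0.58
CA	-1.45
GT	-1.44
CT	-1.28
GA	-1.30
CG	-2.17
GC	-2.24
GG	-1.84
TT	-1.00
AC	-1.44
AG	-1.28
TC	-1.30
CC	-1.84
TG	-1.45
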