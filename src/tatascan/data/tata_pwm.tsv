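# tatascan default TATA-box position frequency matrix, v1.
# 15 positions; core TATAWAWR consensus at offsets 3..10, weakly GC-biased
# upstream flank and weakly G-biased downstream flank.  Frequencies per row
# sum to 1; scores are log(freq/0.25).
position	A	C	G	T
0	0.22	0.28	0.28	0.22
1	0.22	0.28	0.28	0.22
2	0.22	0.28	0.28	0.22
3	0.05	0.08	0.04	0.83
4	0.89	0.03	0.03	0.05
5	0.07	0.03	0.02	0.88
6	0.91	0.02	0.02	0.05
7	0.60	0.03	0.04	0.33
8	0.83	0.04	0.05	0.08
9	0.50	0.07	0.08	0.35
10	0.42	0.10	0.38	0.10
11	0.20	0.27	0.33	0.20
12	0.20	0.27	0.33	0.20
13	0.20	0.27	0.33	0.20
14	0.20	0.27	0.33	0.20
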