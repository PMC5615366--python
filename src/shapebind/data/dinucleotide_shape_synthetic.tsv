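# Synthetic stand-in for a dinucleotide structural-property table.
# Values are representative B-DNA dinucleotide step/groove parameters
# compiled from published crystallographic averages (helix twist and
# roll in degrees, minor groove width in Angstrom, propeller twist in
# degrees); they follow reverse-complement symmetry.  They are NOT an
# export of any database; model code treats them as an opaque K x 16
# matrix and, by default, z-scores each feature across the 16
# dinucleotides before fitting.
dinucleotide	twist	minor_groove_width	propeller_twist	roll
AA	35.1	2.98	-18.66	0.7
AC	31.5	3.38	-13.10	1.1
AG	31.9	3.26	-14.00	4.5
AT	29.3	3.02	-15.01	1.1
CA	37.3	3.49	-9.45	4.7
CC	32.9	3.28	-8.11	3.6
CG	36.1	3.69	-10.03	5.4
CT	31.9	3.26	-14.00	4.5
GA	36.3	3.32	-13.48	1.9
GC	33.6	3.55	-11.08	0.3
GG	32.9	3.28	-8.11	3.6
GT	31.5	3.38	-13.10	1.1
TA	37.8	3.70	-11.85	3.3
TC	36.3	3.32	-13.48	1.9
TG	37.3	3.49	-9.45	4.7
TT	35.1	2.98	-18.66	0.7
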