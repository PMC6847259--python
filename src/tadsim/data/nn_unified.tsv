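# Unified oligonucleotide nearest-neighbor parameters for DNA/DNA duplexes in 1 M NaCl.
# stack: 5'XY3' paired with its complement (10 unique stacks).
# dH in kcal/mol, dS in cal/(mol K).
stack	dH	dS
AA/TT	-7.9	-22.2
AT/TA	-7.2	-20.4
TA/AT	-7.2	-21.3
CA/GT	-8.5	-22.7
GT/CA	-8.4	-22.4
CT/GA	-7.8	-21.0
GA/CT	-8.2	-22.2
CG/GC	-10.6	-27.2
GC/CG	-9.8	-24.4
GG/CC	-8.0	-19.9
init	0.2	-5.7
term_AT	2.2	6.9
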