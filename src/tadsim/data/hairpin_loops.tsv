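# Hairpin loop free-energy increments at 37 C (kcal/mol), entropic by convention
# (dH = 0, dS = -1000*dG37/310.15). Linear interpolation between tabulated sizes;
# Jacobson-Stockmayer extrapolation beyond the largest tabulated size.
loop_nt	dG37
3	3.5
4	3.5
5	3.3
6	4.0
7	4.2
8	4.3
9	4.5
10	4.4
12	4.6
14	4.7
16	4.9
18	4.9
20	5.1
25	5.3
30	5.5
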