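# 3' splice-acceptor consensus frequency table (Shapiro–Senapathy style).
# One row per window position, columns: position label, then the frequency of
# A, C, G, T at that position.  Positions -10..-1 are intronic (the invariant
# AG occupies -2/-1 with frequency 1), +1..+6 are exonic.  Rows sum to 1.
# The consensus value of a window w is 100*(t(w)-t_min)/(t_max-t_min) where
# t(w) sums the per-position frequencies of the observed bases.
pos	A	C	G	T
-10	0.15	0.30	0.10	0.45
-9	0.12	0.32	0.08	0.48
-8	0.10	0.32	0.08	0.50
-7	0.10	0.35	0.07	0.48
-6	0.12	0.35	0.06	0.47
-5	0.10	0.38	0.06	0.46
-4	0.24	0.30	0.05	0.41
-3	0.06	0.72	0.02	0.20
-2	1.00	0.00	0.00	0.00
-1	0.00	0.00	1.00	0.00
+1	0.25	0.12	0.50	0.13
+2	0.25	0.20	0.20	0.35
+3	0.25	0.25	0.25	0.25
+4	0.25	0.25	0.25	0.25
+5	0.25	0.25	0.25	0.25
+6	0.25	0.25	0.25	0.25
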