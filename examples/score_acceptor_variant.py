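"""Score a 3' acceptor before and after a variant, and call loss/gain.

Builds the MSH2-like toy gene, scores the intron-4 acceptor with the shipped
consensus-value matrix for the wild-type and the c.793-1G>A junction, and
prints the relative change.  A negative percent change at or below -10%
is called a site loss; the same arithmetic applied to score pairs from
external predictors gives their published deltas.
"""

import splicelens as sl

gene = sl.make_toy_gene(sl.mshlike_spec(seed=17))
report = sl.run_pipeline(gene, "c.793-1G>A")
ca = report["canonical_acceptor"]

print(f"canonical acceptor of intron {ca['intron']}:")
print(f"  WT CV     = {ca['wt_score']}")
print(f"  mutant CV = {ca['mut_score']}")
print(f"  delta     = {ca['percent_change']}%  ->  {ca['call']}")
print()
print("same delta arithmetic on external predictor score pairs:")
for wt, mut in [(86.74, 58.87), (10.35, 1.6), (-2.15, 5.8)]:
    print(f"  {wt} -> {mut}: {sl.percent_change(wt, mut):+.2f}%")
# The first pair is a canonical-site loss, the last a new-site gain; the
# percent change uses |WT| in the denominator so a negative baseline keeps
# a meaningful sign.
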