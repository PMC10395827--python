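"""Triage a suspected Lynch-syndrome family with the rule engines.

Evaluates the NCI five-marker MSI panel, infers the mutated MMR gene from
the IHC loss patterns, and checks the Amsterdam II pedigree criteria on the
bundled four-generation family fixture.
"""

import splicelens as sl

bundle = sl.make_clinical_fixtures(seed=17)

msi = sl.classify_msi(bundle.msi_calls)
print(f"MSI panel: {sum(c == 'unstable' for c in bundle.msi_calls.values())}/5 "
      f"unstable -> fraction {msi.fraction_unstable:.2f} -> {msi.msi_class}")

for sample, pattern in sorted(bundle.ihc_patterns.items()):
    lost = ", ".join(sorted(pattern.lost())) or "none"
    genes = sl.infer_mmr_gene(pattern)
    print(f"IHC {sample}: lost [{lost}] -> candidate gene {genes[0]}")

res = sl.amsterdam_ii(bundle.pedigree)
print(f"Amsterdam II met: {res.met}")
for criterion, value in res.breakdown.items():
    print(f"  {criterion}: {value}")
# MSI-H plus MSH2/MSH6 loss on IHC plus a pedigree meeting Amsterdam II is
# the triad that prioritises MSH2 for germline testing.
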