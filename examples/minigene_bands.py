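"""Plan a minigene splicing assay and predict its RT-PCR band table.

Assembles the exon/intron-part/exon construct (147 + 1,708 + 150 = 2,005 bp
insert, 160 nt of transcribed vector flank), predicts the product size of
each isoform, and prints the Sanger-verification k-mers across each splice
junction.
"""

import splicelens as sl

bundle = sl.make_clinical_fixtures(seed=17)
gene, construct = bundle.gene, bundle.construct

print(f"insert length: {construct.insert_length} bp "
      f"(exons {[s.length for s in construct.exon_segments]}, "
      f"intron part {construct.intron_segments[0].length})")

report = sl.run_pipeline(gene, "c.793-1G>A", construct=construct)
wt = report["minigene"]["wt_rtpcr_size"]
print(f"WT RT-PCR product: {wt} bp "
      f"({construct.flank_total} bp vector + {wt - construct.flank_total} bp target)")

isoforms = {iso["kind"]: iso for iso in report["isoforms"]}
for kind, iso in isoforms.items():
    print(f"  {kind:<18} band: {iso['rtpcr_size']} bp ({iso['rtpcr_size'] - wt:+d} vs WT)")

normal = sl.normal_transcript(gene)
trunc = next(t for t in sl.enumerate_outcomes(
    gene, sl.parse_hgvs_c("c.793-1G>A"),
    [sl.AcceptorSite(0, "", 0.0)],
))
print("junction 8-mers for Sanger verification:")
print("  WT        :", sl.junction_strings(construct, normal, k=8)[0])
print("  truncation:", sl.junction_strings(construct, trunc, k=8)[0])
# The truncated band runs 1 bp below the 457-bp WT product and the retained
# band 51 bp above it; the junction k-mers are what a Sanger trace across the
# novel junction should read.
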