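"""Reconstruct the aberrant isoforms implied by an acceptor loss.

Runs the full pipeline on the MSH2-like gene with c.793-1G>A and prints one
line per candidate isoform: the cDNA change, the protein-level frameshift
annotation, the truncated-protein length, and whether the premature stop is
predicted to trigger nonsense-mediated decay (50-nt rule).
"""

import splicelens as sl

gene = sl.make_toy_gene(sl.mshlike_spec(seed=17))
report = sl.run_pipeline(gene, "c.793-1G>A")

print(f"{'rank':<5}{'kind':<18}{'nt':>4}  {'cDNA':<16}{'protein':<20}{'aa':>4}  NMD")
for iso in report["isoforms"]:
    print(
        f"{iso['rank']:<5}{iso['kind']:<18}{iso['nt_delta']:>+4}  "
        f"{iso['cdna_hgvs']:<16}{iso['hgvs_p']:<20}"
        f"{iso['truncated_length']:>4}  {iso['nmd_predicted']}"
    )
# Two outcomes compete for the destroyed acceptor: the AG formed at the
# junction (1-nt exon truncation) and the planted intronic AG 51 nt upstream
# (intron retention); both frameshift annotations end in early stops, so both
# truncated proteins (272 and 278 aa) are far shorter than the 469-aa normal.
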