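# splicelens

Splice-acceptor variant consequence analysis for clinical genetics, built
around the kind of workup done for an intronic acceptor variant in a
mismatch-repair gene (the motivating case is MSH2 c.793-1G>A in a
Lynch-syndrome family): how badly is the 3' splice site damaged, which
cryptic AG takes over, what do the resulting transcripts and truncated
proteins look like, what bands would a minigene assay show, and does the
family's clinical picture (MSI, IHC, pedigree) point at the same gene?

It is a library, used from Python; `examples/` holds one short narrative
script per capability.

## What it computes

**Acceptor strength and deltas.** A 3' acceptor window (10 intronic + 6
exonic nt around the invariant AG) is scored with a Shapiro–Senapathy-style
consensus value

CV(w) = 100 · (t(w) − t_min) / (t_max − t_min),  t(w) = Σᵢ fᵢ(wᵢ),

where fᵢ are per-position nucleotide frequencies; the per-position modal
window scores exactly 100. Variant impact is the relative change
ΔCV = 100 · (CV_mut − CV_wt) / |CV_wt|, with loss called at ΔCV ≤ −10% and
a non-canonical gain at ΔCV ≥ +10% (configurable). The same arithmetic
applies to score pairs printed by external predictors (HSF, SpliceAI, ...),
which are treated as inputs, never reimplemented.

**Cryptic-site scanning and isoform reconstruction.** Every AG in a window
around the disrupted acceptor (default 100 nt into the intron, 25 nt into
the exon) is scored and ranked. An AG at or inside the downstream exon
implies an exon truncation; an AG upstream in the intron implies retention
of the intronic bases 3' of it; exon skipping is an optional third outcome.
Each isoform is translated from c.1 to its first premature termination
codon (PTC). Frameshift nomenclature follows HGVS counting: in
`p.<Ref><pos><Alt>fs*<N>` the first changed residue is 1, so the truncated
protein has `pos + N − 2` residues, and NMD is predicted by the 50-nt rule
(PTC more than 50 nt upstream of the final exon–exon junction).

**Minigene arithmetic.** Insert length, RT-PCR product sizes per isoform
(vector flank + exonic content; an aberrant band shifts by exactly the
isoform's nt delta), and junction k-mers for Sanger verification.

**Clinical rules.** NCI five-marker MSI panel (MSI-H at ≥ 40% unstable
markers), IHC loss-pattern → MMR-gene inference via the MSH2–MSH6 /
MLH1–PMS2 heterodimer logic, and the Amsterdam II pedigree criteria.

**Synthetic data.** `make_toy_gene` builds audited toy genes with planted
cryptic AGs and engineered stops so every number above is predictable;
`mshlike_spec()` is the preset that mirrors the motivating case, and
`make_clinical_fixtures` adds a matching pedigree/MSI/IHC bundle.

## Worked example

```python
import splicelens as sl

gene = sl.make_toy_gene(sl.mshlike_spec(seed=17))
report = sl.run_pipeline(gene, "c.793-1G>A")
for iso in report["isoforms"]:
    print(iso["cdna_hgvs"], iso["hgvs_p"], iso["truncated_length"], iso["nmd_predicted"])
```

prints

```
c.792_793ins51 p.Val265Asnfs*15 278 True
c.793del p.Val265Leufs*9 272 True
```

i.e. the destroyed acceptor is replaced by two competing AGs: the one
formed at the mutated junction removes the first base of the downstream
exon (1-nt truncation, frameshift, stop 9 codons later, 272-aa protein),
and the planted intronic AG 51 nt upstream retains 51 intronic bases
(insertion, Asn at codon 265, stop at new-frame codon 15, 278-aa protein).
Both PTCs lie far upstream of the last exon junction, so both transcripts
are predicted NMD substrates. With the matching minigene construct
(`sl.minigene_from_gene(gene, 5)`), the predicted RT-PCR bands are 457 bp
(full length: 160 bp vector flank + 297 bp of exon), 456 bp (truncation)
and 508 bp (retention). `examples/` walks through scoring, reconstruction,
minigene planning, clinical triage and fixture simulation, each printing
the numbers above with a line on what they mean.

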