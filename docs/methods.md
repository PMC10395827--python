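# Methods

## Scope and model

splicelens models the desk-side half of a splice-acceptor variant workup:
given a plus-strand coding gene model (ordered exons/introns with sequence)
and a variant in a supported HGVS c. subset, it quantifies acceptor damage,
enumerates replacement acceptors, reconstructs the implied mRNAs, translates
them to premature stops, predicts minigene band sizes, and evaluates the
rule-based clinical criteria used to triage Lynch-syndrome families. The
wet-lab half (staining, electropherograms, gels) and the internals of
external splice predictors are out of scope by design: external predictor
scores enter only as numbers whose deltas and calls the package computes.

## Coordinate conventions

Internally all coordinates are 0-based half-open; the HGVS c. surface
(1-based CDS positions, signed intronic offsets) is converted in
`gene_model` and nowhere else. Intron *i* follows exon *i*; `c.N-k`
resolves to position `len(intron) - k` of the intron preceding the exon
containing c.N, and the anchor base must be exon-adjacent. Only plus-strand
models are accepted; minus-strand input is rejected rather than silently
reverse-complemented. The CDS is taken to run from `cds_start_in_transcript`
to the transcript end; UTR positions (c.-N, c.*N) are unsupported.

## Acceptor scoring

The score is a Shapiro–Senapathy-style consensus value over a 16-nt window
(intronic −10..−1, exonic +1..+6, invariant AG fixed at −2/−1):
`CV = 100·(t − t_min)/(t_max − t_min)` with `t` the sum of per-position
frequencies of the observed bases. This makes the modal window score
exactly 100 and makes the score monotone: moving any position away from its
modal base can never raise the CV. The shipped frequency table
(`data/acceptor_3ss.tsv`) is authored for this package — a polypyrimidine
tract rising toward the 3' end, a strongly C-biased −3, the invariant AG,
a G-preferring +1 and uninformative distal exonic positions. It is
internally consistent rather than fitted to a genome-scale alignment, so
absolute CVs are not comparable to HSF's; the delta arithmetic and calls
are score-family-agnostic. `percent_change` divides by |WT| so a
negative-baseline gain keeps a positive sign. Default call thresholds are
±10%, the convention commonly used for consensus-value interpretation;
both are configurable.

## Cryptic scan and isoform reconstruction

The scan window defaults to 100 nt into the intron and 25 nt into the exon
from the disrupted acceptor — wide enough to cover retention events of
realistic size and truncations well past the published 51-nt/1-nt pair,
narrow enough that everything found is plausibly junction-proximal. Sites
are ranked by score, ties broken by proximity to the canonical position.
AGs at the canonical dinucleotide itself are never replacement candidates.
An AG whose G sits at exon offset d ≥ 0 yields an exon truncation of d+1
bases (`c.<first>del` / `c.<first>_<last>del`); an AG fully inside the
intron retains the bases 3' of it (`c.<N-1>_<N>ins<len>`; the normalized
`insNN` form is emitted, with the explicit sequence carried separately).
Exon skipping is enumerated on request; no ranking is imposed between
reconstruction kinds because minigene data show competing products can
co-occur.

## Translation, fs*N and NMD

Each isoform is translated from c.1 with the standard code. The first
residue differing from the normal protein defines the first affected codon;
the first stop in the aberrant frame gives the fs*N offset (first changed
residue = 1), so truncated length = first codon + N − 2 — the formula is
cross-checked against a literal codon walk in the tests on a thousand
random genes. A stop at the first changed codon is reported as nonsense
(`p.Xpos*`), an unchanged protein as `p.(=)`, and a stop-free aberrant
frame is flagged as an extension rather than raising. The `frameshift`
boolean strictly follows nt_delta mod 3; the rendered HGVS string uses the
clinical `fs*N` form whenever a novel residue run ends at a PTC, including
in-frame insertions that contain their own stop — that is how such events
are reported in practice, and the arithmetic is identical. NMD is the
classic 50-nt rule against the final exon–exon junction of the *aberrant*
transcript, with the distance configurable; single-exon transcripts never
qualify.

## Minigene arithmetic

A construct is an ordered list of exon / intron-part / vector-flank
segments. Only the total transcribed flank length affects RT-PCR product
sizes, so the 5'/3' split defaults to all-5'. The full-length product is
flank + Σ exon lengths; each aberrant product shifts by exactly the
isoform's nt delta, which is also asserted as a property. Restriction
sites are labels only.

## Clinical rules

MSI: fraction of unstable markers ≥ 0.40 → MSI-H (the published panel
threshold); any instability below that → MSI-L (Bethesda convention, which
the source only implies); none → MSS. Unknown marker names are counted
with a warning. IHC: within each heterodimer the obligate partner
dominates — MSH2 loss (alone or with MSH6) → MSH2; isolated MSH6 loss →
MSH6; mirrored for MLH1/PMS2; loss on both axes returns both candidates.
Amsterdam II: ≥ 3 LS-spectrum-affected relatives with one a first-degree
relative of the other two, affected members in two successive generation
levels (founders = generation 1), ≥ 1 diagnosis before 50, plus FAP
exclusion and pathology verification accepted as boolean attestations.
The default spectrum is {colorectal, endometrial, small bowel, ureter,
renal pelvis}. Affected individuals with no resolvable kinship make the
first-degree criterion indeterminate and the overall result "not
evaluable" instead of silently false.

## Synthetic data

The generator emulates the structure the pipeline assumes, not real MSH2:
random sense codons form the CDS, introns get GT/AG termini, and the
studied junction is engineered — exon-start motif (GTTGCA ⇒ Val at the
first exon codon), intron-end decamer (TTAATTTTAG), cryptic AGs planted at
requested distances from the intron end, and stop codons placed so the
first stop after a 1-nt truncation and after retention fall at requested
new-frame indices. Repairs use a single trick: setting a base to C can
neither create a stop codon nor an AG, so stop-derailing and AG-scrubbing
cannot undo each other. With 51 retained bases the intron-end decamer
itself supplies the retention-frame stop at codon 15, which the generator
verifies rather than plants. Every gene is audited after construction
(exact AG census in the scan window, first-stop positions by literal
translation walks, single terminal stop in the normal frame); generation is
deterministic per seed with bounded retries. The MSH2-like preset uses
exon lengths (215, 215, 215, 147, 150, 183, 162, 123) — 264 codons before
the studied junction, the published 147/1,708/150 core, and 470 codons in
total — and 200-nt background introns to keep tests fast. What passing
tests show is therefore that the *arithmetic and reconstruction logic* are
correct on genes with the assumed structure; they say nothing about real
splice-site strength landscapes, branch points, or tissue-specific splicing
efficiency, none of which are modelled.

Clinical fixtures mirror the shape of the motivating family: a
four-generation pedigree with an affected sibship of sisters in generation
II and early-onset colorectal/endometrial cancers in generation III, an
MSI record with 2–5 unstable markers (seed-dependent, always ≥ the MSI-H
threshold), and the two observed IHC patterns (MSH2−/MSH6− and MSH2− with
MSH6 retained).

## Numerical and degenerate-input choices

Percent changes are exact floats, rounded to two decimals only at the
report surface. A zero wild-type score makes the delta undefined and
raises. AGs too close to a sequence end to fill the scoring window are
reported with −inf score (they sort last) rather than being hidden.
Empty scan windows return empty lists; an empty FASTA warns and returns
nothing; reference-base mismatches and intron-boundary overruns raise
typed errors rather than guessing. Reports are canonicalised through JSON
with sorted keys, so identical inputs produce byte-identical output.

## Known limitations

Donor-site consequences, branch-point/polypyrimidine modelling, multi-
intron compound events and quantitative isoform usage are not modelled.
The HGVS parser covers only the subset the pipeline needs (substitutions,
single-base deletions, flanked insertions); VCF input is SNV-only. The
shipped matrix is illustrative, not population-calibrated. Risk models
(e.g. logistic pedigree scores) are out of scope; the clinical engines are
deliberately rule-based and transparent.
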