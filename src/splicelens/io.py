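"""File I/O: FASTA, the gene-model/construct JSON dialect, pedigree TSV, VCF.

Gene models and minigene constructs travel as a small documented JSON
dialect (one record per exon/intron segment: role, index, length, sequence);
sequences travel as standard FASTA via Biopython; pedigrees as a PED-like
TSV extended with diagnosis columns; variants as HGVS c. strings or a
minimal VCF read through pysam and mapped onto the gene model.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clinical import Diagnosis, PedigreeIndividual
from .gene_model import GeneModel, SpliceVariant, hgvs_from_genomic
from .minigene import MinigeneConstruct, Segment

_NT = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Malformed or non-ACGT FASTA content."""


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}, uppercase-normalised, ACGT-only.

    An empty file yields an empty dict with a warning; non-ACGT characters
    are rejected with the offending record and position.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, c in enumerate(seq):
            if c not in _NT:
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} has non-ACGT character {c!r} "
                    f"at position {i + 1}"
                )
        out[rec.id] = seq
    if not out:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    """Write {id: sequence} as FASTA wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- gene-model JSON dialect ---------------------------------------------


def gene_to_json(gene: GeneModel, path=None) -> dict:
    """Serialise a gene model; writes to ``path`` when given."""
    doc = {
        "name": gene.name,
        "chrom": gene.chrom,
        "strand": gene.strand,
        "genomic_offset": gene.genomic_offset,
        "cds_start_in_transcript": gene.cds_start_in_transcript,
        "segments": [],
    }
    for i, seq in enumerate(gene.exons, start=1):
        doc["segments"].append(
            {"role": "exon", "index": i, "length": len(seq), "sequence": seq}
        )
        if i <= len(gene.introns):
            iseq = gene.introns[i - 1]
            doc["segments"].append(
                {"role": "intron", "index": i, "length": len(iseq), "sequence": iseq}
            )
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def gene_from_json(source) -> GeneModel:
    """Load a gene model from a JSON file path or an already-parsed dict."""
    doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    exons, introns = [], []
    for seg in doc["segments"]:
        if seg["length"] != len(seg["sequence"]):
            raise ValueError(
                f"{seg['role']} {seg['index']}: declared length {seg['length']} "
                f"!= sequence length {len(seg['sequence'])}"
            )
        (exons if seg["role"] == "exon" else introns).append(seg["sequence"])
    return GeneModel(
        doc["name"],
        exons,
        introns,
        chrom=doc.get("chrom", "chrN"),
        strand=doc.get("strand", "+"),
        cds_start_in_transcript=doc.get("cds_start_in_transcript", 0),
        genomic_offset=doc.get("genomic_offset", 0),
    )


def construct_to_json(construct: MinigeneConstruct, path=None) -> dict:
    doc = {
        "flank_5": construct.flank_5,
        "flank_3": construct.flank_3,
        "cloning_sites": list(construct.cloning_sites),
        "segments": [
            {"label": s.label, "role": s.role, "length": s.length, "sequence": s.sequence}
            for s in construct.segments
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def construct_from_json(source) -> MinigeneConstruct:
    doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    return MinigeneConstruct(
        [Segment(s["label"], s["role"], s["length"], s.get("sequence")) for s in doc["segments"]],
        flank_5=doc.get("flank_5", 0),
        flank_3=doc.get("flank_3", 0),
        cloning_sites=tuple(doc.get("cloning_sites", ("XhoI", "EcoRI"))),
    )


# -- pedigree TSV ---------------------------------------------------------

_PED_COLUMNS = ["id", "sex", "father", "mother", "carrier", "diagnoses"]


def write_pedigree_tsv(pedigree: list[PedigreeIndividual], path) -> None:
    """PED-like TSV; diagnoses serialised as ``type@age`` joined by ';'."""
    rows = []
    for p in pedigree:
        diag = ";".join(
            f"{d.cancer_type}@{d.age if d.age is not None else '?'}" for d in p.diagnoses
        )
        rows.append(
            {
                "id": p.id,
                "sex": p.sex,
                "father": p.father or ".",
                "mother": p.mother or ".",
                "carrier": {True: "1", False: "0", None: "."}[p.carrier],
                "diagnoses": diag or ".",
            }
        )
    pd.DataFrame(rows, columns=_PED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> list[PedigreeIndividual]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    out = []
    for _, row in df.iterrows():
        diagnoses = []
        if row["diagnoses"] != ".":
            for item in row["diagnoses"].split(";"):
                ctype, age = item.rsplit("@", 1)
                diagnoses.append(Diagnosis(ctype, None if age == "?" else int(age)))
        out.append(
            PedigreeIndividual(
                id=row["id"],
                sex=row["sex"],
                father=None if row["father"] == "." else row["father"],
                mother=None if row["mother"] == "." else row["mother"],
                diagnoses=diagnoses,
                carrier={"1": True, "0": False, ".": None}[row["carrier"]],
            )
        )
    return out


# -- VCF ------------------------------------------------------------------


def read_vcf_variants(path, gene: GeneModel) -> list[SpliceVariant]:
    """Map the SNV records of a minimal VCF onto the gene model as HGVS c.

    Records on other contigs are skipped with a warning; non-SNV records
    raise, per the v1 contract.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.chrom != gene.chrom:
                warnings.warn(
                    f"skipping {rec.chrom}:{rec.pos}, gene is on {gene.chrom}",
                    stacklevel=2,
                )
                continue
            for alt in rec.alts or ():
                out.append(hgvs_from_genomic(gene, rec.pos, rec.ref, alt))
    return out


def write_fixture_bundle(bundle, outdir) -> dict[str, Path]:
    """Write a FixtureBundle to a directory: FASTA + gene JSON + variants +
    pedigree/MSI/IHC records.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene = bundle.gene
    paths = {
        "fasta": outdir / f"{gene.name}.fa",
        "gene": outdir / f"{gene.name}.gene.json",
        "construct": outdir / f"{gene.name}.minigene.json",
        "variants": outdir / "variants.txt",
        "pedigree": outdir / "pedigree.tsv",
        "msi": outdir / "msi.json",
        "ihc": outdir / "ihc.json",
    }
    seqs = {f"{gene.name}_exon{i + 1}": s for i, s in enumerate(gene.exons)}
    seqs.update({f"{gene.name}_intron{i + 1}": s for i, s in enumerate(gene.introns)})
    write_fasta(paths["fasta"], seqs)
    gene_to_json(gene, paths["gene"])
    construct_to_json(bundle.construct, paths["construct"])
    paths["variants"].write_text("\n".join(bundle.variants) + "\n")
    write_pedigree_tsv(bundle.pedigree, paths["pedigree"])
    paths["msi"].write_text(json.dumps(bundle.msi_calls, indent=1, sort_keys=True))
    paths["ihc"].write_text(
        json.dumps(
            {
                k: {g: getattr(p, g) for g in ("mlh1", "msh2", "msh6", "pms2")}
                for k, p in bundle.ihc_patterns.items()
            },
            indent=1,
            sort_keys=True,
        )
    )
    return paths
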