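"""End-to-end acceptor-variant analysis: score, scan, reconstruct, report.

``run_pipeline`` ties the stages together the way a variant-interpretation
workup proceeds: score the canonical acceptor before and after the variant,
call loss/gain, scan the mutant junction region for replacement AG sites,
reconstruct the implied isoforms, translate each to its PTC, predict the
minigene RT-PCR band table, and fold in any clinical rule results.  The
report is a plain JSON-serialisable dict, deterministic for given inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clinical import (
    DEFAULT_LS_SPECTRUM,
    IhcPattern,
    PedigreeIndividual,
    amsterdam_ii,
    classify_msi,
    infer_mmr_gene,
)
from .consequence import enumerate_outcomes, normal_transcript, translate_to_ptc
from .gene_model import GeneModel, SpliceVariant, parse_hgvs_c, resolve_variant
from .minigene import MinigeneConstruct, rtpcr_size
from .splice_sites import (
    ScoreMatrix,
    SpliceDelta,
    call_site,
    canonical_acceptor_window,
    scan_cryptic_acceptors,
    score_acceptor,
)

logger = logging.getLogger("splicelens")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is part of the message."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Tunable knobs of the pipeline, with their working defaults.

    Windows are in nucleotides around the disrupted acceptor (into the
    intron / into the exon); thresholds are relative-change percents for the
    loss/gain calls; ``nmd_rule_nt`` is the PTC-to-last-junction distance of
    the 50-nt rule; ``msi_h_threshold`` the MSI-H marker fraction.
    """

    matrix_path: str | None = None
    intron_window: int = 100
    exon_window: int = 25
    loss_threshold: float = -10.0
    gain_threshold: float = 10.0
    nmd_rule_nt: int = 50
    msi_h_threshold: float = 0.40
    ls_spectrum: tuple[str, ...] = tuple(sorted(DEFAULT_LS_SPECTRUM))
    include_skip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_threshold >= 0 or self.gain_threshold <= 0:
            raise ValueError("loss_threshold must be < 0 and gain_threshold > 0")
        if not 0 < self.msi_h_threshold <= 1:
            raise ValueError("msi_h_threshold must lie in (0, 1]")
        if self.intron_window < 0 or self.exon_window < 0:
            raise ValueError("scan windows must be >= 0")

    def matrix(self) -> ScoreMatrix:
        if self.matrix_path:
            return ScoreMatrix.from_tsv(self.matrix_path)
        return ScoreMatrix.default()

    def to_json(self, path=None) -> dict:
        doc = dataclasses.asdict(self)
        doc["ls_spectrum"] = list(self.ls_spectrum)
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
        return doc

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        doc = dict(doc)
        if "ls_spectrum" in doc:
            doc["ls_spectrum"] = tuple(doc["ls_spectrum"])
        return cls(**doc)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("score")
def _score_canonical(gene, v, coord, matrix):
    """WT vs mutant consensus value of the acceptor nearest the variant."""
    if coord.region == "intron":
        intron_idx = coord.index
    else:
        intron_idx = coord.index - 1 if coord.index > 1 else None
    if intron_idx is None:
        return None, None
    intron = gene.introns[intron_idx - 1]
    exon = gene.exons[intron_idx]
    wt_window = canonical_acceptor_window(intron, exon, matrix)
    L = len(intron)
    ag_off = matrix.ag_offset
    # index of the varied base inside the window, if it falls there
    if coord.region == "intron":
        widx = coord.offset - (L - 2 - ag_off)
    else:
        widx = ag_off + 2 + coord.offset
    mut_window = wt_window
    if v.kind == "substitution" and 0 <= widx < matrix.window_length:
        mut_window = wt_window[:widx] + v.alt + wt_window[widx + 1 :]
    wt = score_acceptor(matrix, wt_window)
    mut = score_acceptor(matrix, mut_window)
    delta = SpliceDelta(wt, mut)
    call_site(delta, canonical=True)
    return intron_idx, delta


def run_pipeline(
    gene: GeneModel,
    variant: SpliceVariant | str,
    config: RunConfig | None = None,
    *,
    construct: MinigeneConstruct | None = None,
    clinical_inputs: dict | None = None,
) -> dict:
    """Run the full analysis and return a structured report.

    ``clinical_inputs`` may carry ``msi_calls`` (marker -> stable/unstable),
    ``ihc`` (sample -> IhcPattern) and ``pedigree``
    (list of PedigreeIndividual); each present input adds a report section.
    Any stage failure raises :class:`PipelineError` naming the stage; no
    partial report is returned.
    """
    cfg = config or RunConfig()
    matrix = cfg.matrix()

    try:
        v = parse_hgvs_c(variant) if isinstance(variant, str) else variant
        coord = resolve_variant(gene, v)
    except Exception as exc:
        raise PipelineError("parse", exc) from exc

    report: dict = {
        "tool": {"name": "splicelens", "version": __version__},
        "config": cfg.to_json(),
        "gene": {
            "name": gene.name,
            "n_exons": gene.n_exons,
            "exon_lengths": gene.exon_lengths,
            "intron_lengths": gene.intron_lengths,
        },
        "variant": {
            "hgvs_c": v.hgvs,
            "region": coord.region,
            "region_index": coord.index,
            "offset_in_region": coord.offset,
        },
    }

    intron_idx, delta = _score_canonical(gene, v, coord, matrix)
    if delta is not None:
        report["canonical_acceptor"] = {
            "intron": intron_idx,
            "wt_score": round(delta.wt_score, 2),
            "mut_score": round(delta.mut_score, 2),
            "percent_change": round(delta.percent_change, 2),
            "call": delta.call,
        }

    is_acceptor = v.intron_offset in (-1, -2)
    if not is_acceptor:
        report["note"] = "not an acceptor variant; analysis stops after scoring"
        logger.info("variant %s is not an acceptor disruption", v.hgvs)
        return _finish(report)

    try:
        intron = gene.introns[intron_idx - 1]
        exon = gene.exons[intron_idx]
        mut = list(intron)
        if v.kind == "substitution":
            mut[len(intron) + v.intron_offset] = v.alt
        region = "".join(mut) + exon
        L = len(intron)
        sites = scan_cryptic_acceptors(
            region,
            (L - cfg.intron_window, L + cfg.exon_window),
            matrix,
            origin=L,
            canonical_position=-1,
        )
    except Exception as exc:
        raise PipelineError("scan", exc) from exc
    report["candidate_sites"] = [
        {
            "position": s.position,
            "context": s.context,
            "score": round(s.score, 2),
            "provenance": s.provenance,
        }
        for s in sites
    ]

    try:
        transcripts = enumerate_outcomes(gene, v, sites, include_skip=cfg.include_skip)
        normal = normal_transcript(gene)
        isoforms = []
        for rank, t in enumerate(transcripts, start=1):
            pc = translate_to_ptc(gene, t, nmd_rule_nt=cfg.nmd_rule_nt)
            entry = {
                "rank": rank,
                "kind": t.kind,
                "nt_delta": t.nt_delta,
                "cdna_hgvs": t.cdna_hgvs,
                "junction": t.junction_desc,
                "site_position": t.site.position if t.site else None,
                "site_score": round(t.site.score, 2) if t.site else None,
                "hgvs_p": pc.hgvs_p,
                "first_codon": pc.first_codon,
                "stop_offset": pc.stop_offset,
                "truncated_length": pc.truncated_length,
                "frameshift": pc.frameshift,
                "has_ptc": pc.has_ptc,
                "nmd_predicted": pc.nmd_predicted,
            }
            if construct is not None:
                entry["rtpcr_size"] = rtpcr_size(construct, t).size
            isoforms.append(entry)
        report["isoforms"] = isoforms
        if construct is not None:
            report["minigene"] = {
                "insert_length": construct.insert_length,
                "flank_total": construct.flank_total,
                "wt_rtpcr_size": rtpcr_size(construct, normal).size,
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("consequence", exc) from exc

    if clinical_inputs:
        try:
            clin: dict = {}
            if "msi_calls" in clinical_inputs:
                msi = classify_msi(clinical_inputs["msi_calls"], cfg.msi_h_threshold)
                clin["msi"] = {
                    "fraction_unstable": round(msi.fraction_unstable, 4),
                    "class": msi.msi_class,
                }
            if "ihc" in clinical_inputs:
                clin["ihc"] = {
                    sample: {"candidates": infer_mmr_gene(pattern)}
                    for sample, pattern in sorted(clinical_inputs["ihc"].items())
                }
            if "pedigree" in clinical_inputs:
                res = amsterdam_ii(
                    clinical_inputs["pedigree"], spectrum=set(cfg.ls_spectrum)
                )
                clin["amsterdam_ii"] = {"met": res.met, "breakdown": res.breakdown}
            report["clinical"] = clin
        except Exception as exc:
            raise PipelineError("clinical", exc) from exc

    return _finish(report)


def _finish(report: dict) -> dict:
    # round-trip through JSON so the report is exactly what a file would hold
    return json.loads(json.dumps(report, sort_keys=True))


def report_to_json(report: dict) -> str:
    """Canonical serialisation; byte-identical for identical inputs."""
    return json.dumps(report, sort_keys=True, indent=1)
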