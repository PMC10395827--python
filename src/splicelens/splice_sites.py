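"""Acceptor-site scoring, percent-change deltas, loss/gain calls, AG scanning.

The score is a 0–100 consensus value (CV) in the Shapiro–Senapathy style:
per-position nucleotide frequencies are summed over the window and min–max
rescaled so that the per-position modal window scores exactly 100.  The delta
arithmetic (``percent_change``) and the loss/maintained/gain calls operate on
any score pair, including values printed by external predictors (HSF,
SpliceAI, ...) — those tools are treated as score *sources*, never
recomputed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}


class MatrixError(ValueError):
    """Malformed score matrix."""


class ScoringError(ValueError):
    """Window cannot be scored (wrong length or unsupported alphabet)."""


class UndefinedBaselineError(ZeroDivisionError):
    """Percent change is undefined for a zero wild-type score."""


@dataclass
class ScoreMatrix:
    """Per-position nucleotide frequency table for 3' acceptor windows.

    ``weights`` has shape (window_length, 4) with columns in ACGT order;
    ``ag_offset`` is the window index of the invariant A (the G follows).
    """

    weights: np.ndarray
    ag_offset: int
    labels: tuple[str, ...] | None = None
    scale: str = "consensus-0-100"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise MatrixError("weights must be (window_length, 4)")
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise MatrixError("each position's frequencies must sum to 1")
        if not 0 <= self.ag_offset <= self.window_length - 2:
            raise MatrixError("ag_offset outside the window")
        a_row = self.weights[self.ag_offset]
        g_row = self.weights[self.ag_offset + 1]
        if a_row[_IDX["A"]] != 1.0 or g_row[_IDX["G"]] != 1.0:
            raise MatrixError("ag_offset positions must be fixed to A and G")

    @property
    def window_length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_total(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_total(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @classmethod
    def from_tsv(cls, path) -> "ScoreMatrix":
        labels, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("pos\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise MatrixError(f"expected 5 columns, got {line!r}")
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        weights = np.array(rows)
        try:
            ag = labels.index("-2")
        except ValueError as exc:
            raise MatrixError("matrix must label the invariant A position '-2'") from exc
        return cls(weights, ag, tuple(labels))

    def to_tsv(self, path) -> None:
        labels = self.labels or tuple(str(i) for i in range(self.window_length))
        with open(path, "w") as fh:
            fh.write("pos\tA\tC\tG\tT\n")
            for lab, row in zip(labels, self.weights):
                fh.write(lab + "\t" + "\t".join(f"{x:.4f}" for x in row) + "\n")

    @classmethod
    def default(cls) -> "ScoreMatrix":
        """The acceptor consensus table shipped with the package (16-mer)."""
        ref = resources.files("splicelens.data") / "acceptor_3ss.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass
class AcceptorSite:
    """An AG dinucleotide with its scored context.

    ``position`` is the coordinate of the AG's G relative to the caller's
    origin; when scanning an intron/exon junction region the origin is the
    first exonic base, so the canonical G sits at -1.
    """

    position: int
    context: str
    score: float
    provenance: str = "cryptic"


@dataclass
class SpliceDelta:
    """WT/mutant score pair with the relative change and its call."""

    wt_score: float
    mut_score: float
    percent_change: float = field(init=False)
    call: str | None = None

    def __post_init__(self) -> None:
        self.percent_change = percent_change(self.wt_score, self.mut_score)


def percent_change(wt_score: float, mut_score: float) -> float:
    """Relative score change in percent: ``100*(mut - wt)/|wt|``.

    The absolute wild-type score in the denominator keeps the sign meaningful
    for negative baselines (a -2.15 -> 5.8 gain is +369.77%).
    """
    if wt_score == 0:
        raise UndefinedBaselineError("percent change undefined for wt_score == 0")
    return 100.0 * (mut_score - wt_score) / abs(wt_score)


def score_acceptor(matrix: ScoreMatrix, window: str) -> float:
    """Consensus value (0–100) of a window under the matrix."""
    w = window.upper()
    if len(w) != matrix.window_length:
        raise ScoringError(
            f"window length {len(w)} != matrix window {matrix.window_length}"
        )
    bad = set(w) - set(ALPHABET)
    if bad:
        raise ScoringError(f"unsupported alphabet characters {sorted(bad)}")
    t = float(sum(matrix.weights[i, _IDX[c]] for i, c in enumerate(w)))
    return 100.0 * (t - matrix.min_total) / (matrix.max_total - matrix.min_total)


def scan_cryptic_acceptors(
    seq: str,
    window: tuple[int, int],
    matrix: ScoreMatrix,
    *,
    origin: int = 0,
    canonical_position: int | None = None,
) -> list[AcceptorSite]:
    """Every AG in ``seq[window[0]:window[1]]``, scored and ranked.

    Sites are sorted by score descending; ties go to the site nearest the
    canonical position (when given), then 5'-most.  AGs whose full scoring
    context would run off the sequence get ``-inf`` and sort last.  Reported
    positions are the G's index minus ``origin``.  An empty window yields an
    empty list.
    """
    s = seq.upper()
    start = max(0, window[0])
    end = min(len(s), window[1])
    sites: list[AcceptorSite] = []
    for i in range(start, end - 1):
        if s[i : i + 2] != "AG":
            continue
        g = i + 1
        ws = i - matrix.ag_offset
        we = ws + matrix.window_length
        if 0 <= ws and we <= len(s):
            context = s[ws:we]
            score = score_acceptor(matrix, context)
        else:
            context = s[max(0, ws) : we]
            score = float("-inf")
        pos = g - origin
        prov = "canonical" if canonical_position is not None and pos == canonical_position else "cryptic"
        sites.append(AcceptorSite(pos, context, score, prov))

    def key(site: AcceptorSite):
        prox = (
            abs(site.position - canonical_position)
            if canonical_position is not None
            else site.position
        )
        return (-site.score, prox, site.position)

    return sorted(sites, key=key)


def canonical_acceptor_window(intron_seq: str, exon_seq: str, matrix: ScoreMatrix) -> str:
    """The matrix-sized window centred on the canonical intron-terminal AG."""
    L = len(intron_seq)
    region = intron_seq + exon_seq
    ws = L - 2 - matrix.ag_offset
    we = ws + matrix.window_length
    if ws < 0 or we > len(region):
        raise ScoringError("intron/exon context shorter than the matrix window")
    return region[ws:we]


def call_site(
    delta: SpliceDelta,
    loss_threshold: float = -10.0,
    gain_threshold: float = 10.0,
    *,
    canonical: bool = True,
) -> str:
    """Classify a delta as site_loss / site_maintained / new_site_gain.

    Loss applies to the canonical site when the relative change drops at or
    below ``loss_threshold``; a non-canonical position whose change reaches
    ``gain_threshold`` is a new-site gain.
    """
    if loss_threshold >= 0 or gain_threshold <= 0:
        warnings.warn(
            "loss_threshold should be negative and gain_threshold positive",
            stacklevel=2,
        )
    if canonical and delta.percent_change <= loss_threshold:
        delta.call = "site_loss"
    elif not canonical and delta.percent_change >= gain_threshold:
        delta.call = "new_site_gain"
    else:
        delta.call = "site_maintained"
    return delta.call
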