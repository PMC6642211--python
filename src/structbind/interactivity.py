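"""Structure-stratified interactivity analysis.

Ties together the structural-content scores and the binder counts:
splitting transcripts into equal-size high-structure (HS) and low-structure
(LS) sets, comparing score distributions between them, fitting the
structure-to-binder laws, and the sequence-similarity cluster analysis that
asks whether, among near-identical paralogs, the more structured transcript
has more protein partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .regression import ExponentialRegression, FitResult, ReciprocalRegression


@dataclass
class StratifiedSets:
    """Equal-size top/bottom structural-content strata."""

    fraction: float
    hs_ids: tuple[str, ...]
    ls_ids: tuple[str, ...]


def stratify(scores: Mapping[str, float], fraction: float) -> StratifiedSets:
    """Split ids into the top and bottom ``fraction`` by score.

    Both strata have exactly ``round(fraction * N)`` members and are
    disjoint for fraction <= 0.5.  Ids are ranked once by (score desc,
    id asc); HS takes the head of the ranking and LS the tail, so at a
    score tie the lexicographically smaller id goes to the higher stratum.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    items = list(scores.items())
    if len(items) < 2:
        raise DegenerateInputError("need at least 2 scored transcripts")
    k = int(round(fraction * len(items)))
    if k < 1:
        raise DegenerateInputError(f"fraction {fraction} selects 0 transcripts")
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    hs_ids = tuple(tid for tid, _ in ranked[:k])
    ls_ids = tuple(tid for tid, _ in ranked[len(ranked) - k:])
    if set(hs_ids) & set(ls_ids):
        raise ValueError("HS and LS sets overlap; reduce the fraction")
    return StratifiedSets(fraction, hs_ids, ls_ids)


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fit_exponential(x, y, loss: Literal["ls", "poisson"] = "ls") -> FitResult:
    """Fit ``y = exp(alpha + beta*x)`` (see :class:`ExponentialRegression`)."""
    return ExponentialRegression(loss=loss).fit_result(np.asarray(x), y)


def fit_reciprocal(x, y) -> FitResult:
    """Fit ``y = 1/(alpha + beta*x)`` (see :class:`ReciprocalRegression`)."""
    return ReciprocalRegression().fit_result(np.asarray(x), y)


# ---------------------------------------------------------------------------
# sequence-similarity clustering (CD-HIT-style greedy representative scheme)


def _aligner(match=1.0, mismatch=0.0, open_gap=-1.0, extend_gap=-0.5):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Global-alignment identity: matches / alignment length (with gaps)."""
    if aligner is None:
        aligner = _aligner()
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cluster_sequences(
    sequences: Mapping[str, str], identity_threshold: float = 0.85
) -> list[list[str]]:
    """Greedy incremental clustering at a global-identity threshold.

    Sequences are processed longest first (ties by id); each joins the first
    cluster whose *representative* (founding sequence) it matches at
    >= ``identity_threshold`` identity, else founds a new cluster.  Mirrors
    the representative-first strategy of CD-HIT without its word filters.
    """
    if not sequences:
        raise DegenerateInputError("no sequences to cluster")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    aligner = _aligner()
    clusters: list[list[str]] = []
    representatives: list[str] = []
    for sid in order:
        seq = sequences[sid]
        for idx, rep in enumerate(representatives):
            if pairwise_identity(seq, rep, aligner) >= identity_threshold:
                clusters[idx].append(sid)
                break
        else:
            clusters.append([sid])
            representatives.append(seq)
    return clusters


@dataclass
class ClusterReport:
    """Per-cluster structure/binder correlation."""

    cluster_id: int
    member_ids: tuple[str, ...]
    pearson_r: float


def paralog_correlation(
    clusters: Iterable[Sequence[str]],
    structure_scores: Mapping[str, float],
    binder_counts: Mapping[str, float],
) -> tuple[list[ClusterReport], float]:
    """Per-cluster Pearson r of (structure score, binder count).

    Members missing either value are dropped; clusters left with fewer than
    two members (or with zero variance in either variable) are excluded.
    Returns the cluster reports and the fraction of clusters with r < 0.
    """
    reports: list[ClusterReport] = []
    for cid, members in enumerate(clusters):
        kept = [m for m in members
                if m in structure_scores and m in binder_counts]
        if len(kept) < 2:
            continue
        xs = np.array([structure_scores[m] for m in kept], dtype=float)
        ys = np.array([binder_counts[m] for m in kept], dtype=float)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        if len(kept) == 2:
            # Pearson r of two distinct points is the sign of the slope
            r = 1.0 if (xs[1] - xs[0]) * (ys[1] - ys[0]) > 0 else -1.0
        else:
            r = float(stats.pearsonr(xs, ys).statistic)
        reports.append(ClusterReport(cid, tuple(kept), r))
    if not reports:
        return [], float("nan")
    fraction_negative = sum(rep.pearson_r < 0 for rep in reports) / len(reports)
    return reports, fraction_negative
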