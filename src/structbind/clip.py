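"""CLIP peak filtering, unique-binder counting and RBP structure preference.

Peak tables carry one row per (transcript, RBP, cell line) binding event with
an input-normalised significance (−log10 p) and fold enrichment (log2 FE).
Stringent filtering keeps roughly the top few percent of events; binder
counts are unique RBPs per transcript with cell lines merged by union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, FormatError

PEAK_COLUMNS = ["transcript_id", "rbp_id", "neglog10_p", "log2_fe"]

#: default stringent cut-offs: -log10(p) > 5 and log2(fold enrichment) > 3
DEFAULT_MIN_NEGLOG10_P = 5.0
DEFAULT_MIN_LOG2_FE = 3.0


def _check_peak_table(peaks: pd.DataFrame) -> None:
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise FormatError(f"peak table missing columns: {sorted(missing)}")


def filter_peaks(
    peaks: pd.DataFrame,
    min_neglog10_p: float = DEFAULT_MIN_NEGLOG10_P,
    min_log2_fe: float = DEFAULT_MIN_LOG2_FE,
) -> pd.DataFrame:
    """Retain peaks strictly above both significance and enrichment cut-offs.

    Row order is preserved; the operation is idempotent.
    """
    _check_peak_table(peaks)
    if not (math.isfinite(min_neglog10_p) or min_neglog10_p == -math.inf):
        raise ValueError("min_neglog10_p must be finite or -inf")
    keep = (peaks["neglog10_p"] > min_neglog10_p) & (peaks["log2_fe"] > min_log2_fe)
    return peaks.loc[keep]


def count_binders(
    peaks: pd.DataFrame,
    transcripts: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Count distinct RBP binders per transcript (cell lines merged by union).

    ``transcripts``, when given, fixes the output universe; transcripts with
    no peaks get a count of 0.  Returns columns transcript_id, n_binders,
    rbp_ids (frozenset).
    """
    _check_peak_table(peaks)
    grouped = peaks.groupby("transcript_id")["rbp_id"].agg(
        lambda s: frozenset(s)
    )
    if transcripts is None:
        index = grouped.index
    else:
        index = pd.Index(transcripts, name="transcript_id")
        grouped = grouped.reindex(index)
    rbp_sets = [s if isinstance(s, frozenset) else frozenset() for s in grouped]
    return pd.DataFrame(
        {
            "transcript_id": index.to_numpy(),
            "n_binders": [len(s) for s in rbp_sets],
            "rbp_ids": rbp_sets,
        }
    )


@dataclass
class PreferenceCall:
    """Structure preference of one RBP versus the transcriptome background."""

    rbp_id: str
    label: Literal["high_structured", "low_structured", "no_preference"]
    p_value: float
    median_targets: float
    median_background: float


def classify_preference(
    rbp_id: str,
    target_scores: Sequence[float],
    background_scores: Sequence[float],
    alpha: float = 0.01,
    test: Literal["mannwhitney", "ks"] = "mannwhitney",
) -> PreferenceCall:
    """Call an RBP's RNA-structure preference.

    Scores must be on a higher-is-more-structured scale (negate chemical-
    reactivity scores first).  The RBP prefers highly structured RNA when
    the median score of its targets exceeds the background median with
    p <= alpha (two-sided Mann-Whitney U by default), prefers low-structured
    RNA for the mirror case, and otherwise has no preference.
    """
    targets = np.asarray(target_scores, dtype=float)
    background = np.asarray(background_scores, dtype=float)
    if targets.size == 0 or background.size == 0:
        raise DegenerateInputError("empty score set")
    if targets.size < 3:
        raise DegenerateInputError("need at least 3 target scores")
    if test == "mannwhitney":
        res = stats.mannwhitneyu(targets, background, alternative="two-sided")
    elif test == "ks":
        res = stats.ks_2samp(targets, background)
    else:
        raise ValueError(f"unknown test {test!r}")
    med_t = float(np.median(targets))
    med_b = float(np.median(background))
    if res.pvalue <= alpha and med_t > med_b:
        label = "high_structured"
    elif res.pvalue <= alpha and med_t < med_b:
        label = "low_structured"
    else:
        label = "no_preference"
    return PreferenceCall(rbp_id, label, float(res.pvalue), med_t, med_b)


def empirical_overlap_p(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: Collection[str],
    n_samples: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Empirical p-value for the overlap of two binder sets.

    Draws ``n_samples`` random subsets of size ``|set_b|`` from the universe
    and compares their overlap with ``set_a`` to the observed one.  Uses the
    add-one estimator ``p = (1 + #{draws with overlap >= observed}) /
    (n_samples + 1)``, so the smallest attainable p is 1/(n_samples+1).
    """
    set_a, set_b = set(set_a), set(set_b)
    universe = sorted(set(universe))
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("set_a and set_b must be subsets of the universe")
    if len(set_b) > len(universe):
        raise ValueError("|set_b| exceeds the universe size")
    observed = len(set_a & set_b)
    rng = np.random.default_rng(seed)
    a_mask = np.isin(universe, sorted(set_a))
    hits = 0
    for _ in range(n_samples):
        draw = rng.choice(len(universe), size=len(set_b), replace=False)
        if int(a_mask[draw].sum()) >= observed:
            hits += 1
    return (1 + hits) / (n_samples + 1)


def read_peaks(path) -> pd.DataFrame:
    """Read a peak TSV with at least the PEAK_COLUMNS columns."""
    df = pd.read_csv(path, sep="\t")
    _check_peak_table(df)
    return df


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False)
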