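"""Differential analysis of an RNA-remodelled protein condensate.

A biotinylated-isoxazole (b-isox) precipitate of cell lysate is incubated
with either a highly structured (HS) or a lowly structured (LS) RNA, and
the precipitate composition is measured by label-free quantification (LFQ)
mass spectrometry: three conditions (background / HS RNA / LS RNA), four
replicates each, with missing values.

The analysis chain is: quantifiability filter (>= 3 valid values in at
least one condition), per-protein two-sample t-test of an RNA condition
against background on log-transformed intensities, released / kept / static
classification at -log10(p) > 1.3, nested stringency tiers of unaffected
proteins, and a rank-sum ROC AUC of interaction-propensity scores against
the release labels.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, FormatError

CONDITIONS = ("background", "hs_rna", "ls_rna")
N_REPLICATES = 4

#: significance threshold on -log10(p) for the released/kept call
SIGNIFICANCE = 1.3
#: |log_ratio| bounds of the high/medium/low stringency tiers
TIER_BOUNDS = {"high": 0.15, "medium": 0.30, "low": 1.0}


def condition_columns(condition: str) -> list[str]:
    return [f"{condition}_{i}" for i in range(1, N_REPLICATES + 1)]


def _check_matrix(matrix: pd.DataFrame) -> None:
    expected = [c for cond in CONDITIONS for c in condition_columns(cond)]
    missing = set(expected) - set(matrix.columns)
    if missing:
        raise FormatError(f"LFQ matrix missing columns: {sorted(missing)}")
    if (matrix[expected] <= 0).any().any():
        raise FormatError("LFQ intensities must be positive where present")


def quantifiable_filter(matrix: pd.DataFrame, min_valid: int = 3) -> pd.DataFrame:
    """Keep proteins with >= min_valid present values in some condition."""
    _check_matrix(matrix)
    keep = np.zeros(len(matrix), dtype=bool)
    for cond in CONDITIONS:
        keep |= matrix[condition_columns(cond)].notna().sum(axis=1) >= min_valid
    return matrix.loc[keep]


def differential(
    matrix: pd.DataFrame,
    rna_condition: Literal["hs_rna", "ls_rna"],
    *,
    log_base: float = 2.0,
    log_transform: bool = True,
    test: Literal["welch", "student"] = "welch",
) -> pd.DataFrame:
    """Per-protein t-test of an RNA condition against background.

    Intensities are log-transformed (base ``log_base``) unless
    ``log_transform`` is off; ``log_ratio`` is the difference of means on
    that scale and ``neglog_p`` is -log10 of the two-sample t-test p-value
    (Welch by default).  Proteins with fewer than two valid values on
    either side are flagged ``untestable``; zero-variance cases degenerate
    to p = 1 (no difference) or p -> 0 (any difference) and are flagged.
    """
    if rna_condition not in ("hs_rna", "ls_rna"):
        raise ValueError("rna_condition must be 'hs_rna' or 'ls_rna'")
    _check_matrix(matrix)
    rows = []
    for pid, row in matrix.iterrows():
        bg = row[condition_columns("background")].dropna().to_numpy(dtype=float)
        rna = row[condition_columns(rna_condition)].dropna().to_numpy(dtype=float)
        if log_transform:
            bg, rna = np.log(bg) / np.log(log_base), np.log(rna) / np.log(log_base)
        if len(bg) < 2 or len(rna) < 2:
            rows.append((pid, math.nan, math.nan, True, False))
            continue
        log_ratio = float(rna.mean() - bg.mean())
        zero_var = bool(np.ptp(bg) == 0 and np.ptp(rna) == 0)
        if zero_var:
            p = 1.0 if log_ratio == 0 else np.finfo(float).tiny
        else:
            res = stats.ttest_ind(rna, bg, equal_var=(test == "student"))
            p = float(res.pvalue)
        rows.append((pid, log_ratio, -math.log10(p), False, zero_var))
    return pd.DataFrame(
        rows,
        columns=["protein_id", "log_ratio", "neglog_p", "untestable",
                 "zero_variance"],
    ).set_index("protein_id")


def classify(
    diff: pd.DataFrame, significance: float = SIGNIFICANCE
) -> pd.Series:
    """Released / kept / static / unquantified labels from a differential.

    released: significantly lower in the RNA condition (neglog_p > 1.3 and
    log_ratio < 0); kept: significantly higher; static: not significant;
    unquantified: untestable.
    """
    labels = pd.Series("static", index=diff.index, name="label")
    sig = diff["neglog_p"] > significance
    labels[sig & (diff["log_ratio"] < 0)] = "released"
    labels[sig & (diff["log_ratio"] > 0)] = "kept"
    labels[diff["untestable"].astype(bool)] = "unquantified"
    return labels


def stringency_tiers(
    diff_hs: pd.DataFrame,
    diff_ls: pd.DataFrame,
    bounds: Mapping[str, float] = TIER_BOUNDS,
    significance: float = SIGNIFICANCE,
) -> dict[str, frozenset]:
    """Nested tiers of proteins unaffected by both RNAs.

    A protein enters a tier when, for *both* RNA conditions, it is
    non-significant (neglog_p < threshold) and |log_ratio| is under the
    tier's bound.  Tighter bounds give smaller sets: high <= medium <= low.
    """
    shared = diff_hs.index.intersection(diff_ls.index)
    tiers: dict[str, frozenset] = {}
    for name, bound in bounds.items():
        members = []
        for pid in shared:
            ok = True
            for diff in (diff_hs, diff_ls):
                row = diff.loc[pid]
                if row["untestable"] or not (
                    row["neglog_p"] < significance
                    and abs(row["log_ratio"]) < bound
                ):
                    ok = False
                    break
            if ok:
                members.append(pid)
        tiers[name] = frozenset(members)
    return tiers


def roc_auc(
    scores: Mapping[str, float],
    positives: Sequence[str],
    negatives: Sequence[str],
) -> float:
    """ROC AUC of scores for positives vs negatives (rank-sum form).

    AUC = P(score_pos > score_neg) + 0.5 * P(tie), computed from midranks,
    which is the Mann-Whitney U statistic normalised by n_pos * n_neg.
    """
    pos, neg = list(positives), list(negatives)
    if not pos or not neg:
        raise DegenerateInputError("both protein groups must be non-empty")
    if set(pos) & set(neg):
        raise ValueError("positive and negative sets overlap")
    missing = [p for p in pos + neg if p not in scores]
    if missing:
        raise KeyError(f"no score for: {missing[:5]}")
    x = np.array([scores[p] for p in pos], dtype=float)
    y = np.array([scores[p] for p in neg], dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
    return float(u / (len(x) * len(y)))


def read_quant_matrix(path) -> pd.DataFrame:
    """Read a wide LFQ TSV: protein_id plus condition_replicate columns."""
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise FormatError("LFQ matrix needs a protein_id column")
    df = df.set_index("protein_id")
    _check_matrix(df)
    return df


def write_quant_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.reset_index().rename(columns={"index": "protein_id"}).to_csv(
        path, sep="\t", index=False
    )
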