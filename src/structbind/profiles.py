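"""Transcript-level structural content from per-nucleotide probing data.

Three kinds of per-nucleotide evidence are supported:

``pars``
    Paired nuclease read counts: V(i) double-strand-specific reads and S(i)
    single-strand-specific reads.  A nucleotide is called double-stranded
    when log10(V/S) > 0, and the transcript's structural content is the
    fraction of such nucleotides.
``dms``
    Chemical-modification read counts where high reactivity marks unpaired
    (single-stranded) nucleotides.  Reads are normalised to the transcript
    maximum and averaged, so *higher* scores mean *less* structure.
``predicted``
    Precomputed per-nucleotide double-strandedness scores from any structure
    predictor; content is the fraction of strictly positive scores.

Scores can be computed with or without the untranslated regions by masking
annotated UTR intervals first (:func:`exclude_regions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ProfileExcluded

ProfileKind = Literal["pars", "dms", "predicted"]


@dataclass
class StructureProfile:
    """Per-nucleotide probing evidence for one transcript.

    ``positions`` are 0-based indices into a transcript of ``length``
    nucleotides; only probed positions need to be present.  Which value
    arrays are set depends on ``kind``: (``ds_reads``, ``ss_reads``) for
    pars, ``reads`` for dms, ``scores`` for predicted.
    """

    transcript_id: str
    kind: ProfileKind
    positions: np.ndarray
    length: int
    ds_reads: Optional[np.ndarray] = None
    ss_reads: Optional[np.ndarray] = None
    reads: Optional[np.ndarray] = None
    scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.length < 1:
            raise FormatError(f"{self.transcript_id}: length must be >= 1")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise FormatError(
                    f"{self.transcript_id}: positions must be strictly increasing"
                )
            if self.positions[0] < 0 or self.positions[-1] >= self.length:
                raise FormatError(
                    f"{self.transcript_id}: positions must lie in [0, length)"
                )
        for name in ("ds_reads", "ss_reads", "reads"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.positions.shape:
                    raise FormatError(f"{self.transcript_id}: {name} shape mismatch")
                if np.any(arr < 0):
                    raise FormatError(f"{self.transcript_id}: {name} must be >= 0")
                setattr(self, name, arr.astype(np.int64))
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.positions.shape:
                raise FormatError(f"{self.transcript_id}: scores shape mismatch")
        required = {"pars": ("ds_reads", "ss_reads"), "dms": ("reads",),
                    "predicted": ("scores",)}
        if self.kind not in required:
            raise FormatError(f"unknown profile kind {self.kind!r}")
        for name in required[self.kind]:
            if getattr(self, name) is None:
                raise FormatError(
                    f"{self.transcript_id}: kind={self.kind} requires {name}"
                )

    @classmethod
    def pars(cls, transcript_id, ds_reads, ss_reads, length=None, positions=None):
        ds_reads = np.asarray(ds_reads)
        if positions is None:
            positions = np.arange(ds_reads.size)
        if length is None:
            length = int(np.max(positions)) + 1 if len(positions) else 1
        return cls(transcript_id, "pars", np.asarray(positions), int(length),
                   ds_reads=ds_reads, ss_reads=np.asarray(ss_reads))

    @classmethod
    def dms(cls, transcript_id, reads, length=None, positions=None):
        reads = np.asarray(reads)
        if positions is None:
            positions = np.arange(reads.size)
        if length is None:
            length = int(np.max(positions)) + 1 if len(positions) else 1
        return cls(transcript_id, "dms", np.asarray(positions), int(length),
                   reads=reads)

    @classmethod
    def predicted(cls, transcript_id, scores, length=None, positions=None):
        scores = np.asarray(scores, dtype=float)
        if positions is None:
            positions = np.arange(scores.size)
        if length is None:
            length = int(np.max(positions)) + 1 if len(positions) else 1
        return cls(transcript_id, "predicted", np.asarray(positions), int(length),
                   scores=scores)


@dataclass
class RegionAnnotation:
    """UTR intervals of one transcript, 0-based half-open."""

    transcript_id: str
    utr5: tuple[int, int] = (0, 0)
    utr3: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("utr5", self.utr5), ("utr3", self.utr3)):
            if lo < 0 or hi < lo:
                raise FormatError(f"{self.transcript_id}: bad {name} interval")


@dataclass
class StructureScore:
    """Transcript-level structural content.

    ``content`` is a fraction in [0, 1]; ``log_content`` its natural log
    (NaN when content is 0); ``n_determined`` the number of nucleotides
    the call is based on.
    """

    transcript_id: str
    content: float
    log_content: float
    n_determined: int
    kind: str = "pars"


def pars_content(
    profile: StructureProfile,
    *,
    pseudocount: float = 0.0,
    denominator: Literal["determined", "full"] = "determined",
) -> StructureScore:
    """Fraction of double-stranded nucleotides from paired nuclease reads.

    Applies the stepwise rule per nucleotide: a position counts as
    double-stranded iff ``log10((V + pseudocount)/(S + pseudocount)) > 0``.
    Positions with ``V + S == 0`` are undetermined and never count; a fully
    undetermined transcript raises :class:`ProfileExcluded` (such transcripts
    are discarded from cohort analyses).

    ``denominator`` selects the normalising length: the number of determined
    nucleotides (default) or the full transcript length.
    """
    if profile.kind != "pars":
        raise FormatError("pars_content requires a pars profile")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    v = profile.ds_reads.astype(float)
    s = profile.ss_reads.astype(float)
    determined = (v + s) > 0
    n_det = int(determined.sum())
    if n_det == 0:
        raise ProfileExcluded(
            f"{profile.transcript_id}: all nucleotides undetermined"
        )
    # theta(log10(V/S)) > 0  <=>  V > S, also correct at S=0 (ratio -> inf)
    # and V=0 (ratio -> 0); pseudocounts shift both sides equally.
    ds = determined & ((v + pseudocount) > (s + pseudocount))
    denom = n_det if denominator == "determined" else profile.length
    content = float(ds.sum()) / denom
    return StructureScore(
        transcript_id=profile.transcript_id,
        content=content,
        log_content=log_content(content) if content > 0 else math.nan,
        n_determined=n_det,
        kind="pars",
    )


def log_content(content: float) -> float:
    """Natural log of a structural-content fraction in (0, 1].

    On this scale a transcript with score −1.3 has ~26–27% double-stranded
    content and one with −2.8 has ~6%.
    """
    if not content > 0:
        raise DegenerateInputError("log_content undefined for content <= 0")
    return math.log(content)


def dms_content(
    profile: StructureProfile, *, min_coverage: float = 0.10
) -> StructureScore:
    """Mean max-normalised chemical reactivity of a transcript.

    Reads are divided by the transcript's maximum read count and averaged
    over the positions present in the profile.  Higher values mean *more
    single-stranded* (the scale is inverted relative to pars).  Transcripts
    whose positions with nonzero reads cover less than ``min_coverage`` of
    the sequence length are excluded (:class:`ProfileExcluded`), as is a
    transcript whose maximum read count is 0.
    """
    if profile.kind != "dms":
        raise FormatError("dms_content requires a dms profile")
    reads = profile.reads.astype(float)
    n_covered = int((reads > 0).sum())
    if n_covered < min_coverage * profile.length:
        raise ProfileExcluded(
            f"{profile.transcript_id}: {n_covered} covered positions "
            f"< {min_coverage:.0%} of length {profile.length}"
        )
    peak = reads.max()
    if peak == 0:
        raise ProfileExcluded(f"{profile.transcript_id}: no reads")
    norm = reads / peak
    return StructureScore(
        transcript_id=profile.transcript_id,
        content=float(norm.mean()),
        log_content=math.nan,
        n_determined=n_covered,
        kind="dms",
    )


def predicted_content(profile: StructureProfile) -> StructureScore:
    """Fraction of nucleotides with a strictly positive predicted score."""
    if profile.kind != "predicted":
        raise FormatError("predicted_content requires a predicted profile")
    if profile.scores.size == 0:
        raise DegenerateInputError(f"{profile.transcript_id}: empty profile")
    content = float((profile.scores > 0).mean())
    return StructureScore(
        transcript_id=profile.transcript_id,
        content=content,
        log_content=log_content(content) if content > 0 else math.nan,
        n_determined=int(profile.scores.size),
        kind="predicted",
    )


def exclude_regions(
    profile: StructureProfile, annotation: RegionAnnotation
) -> StructureProfile:
    """Restrict a profile to positions outside the annotated UTRs.

    The returned profile's ``length`` is the number of nucleotide sites of
    the transcript that fall outside the UTR intervals, so full-length
    normalisation refers to the retained span.
    """
    if annotation.transcript_id != profile.transcript_id:
        raise FormatError("annotation transcript_id does not match profile")
    intervals = [iv for iv in (annotation.utr5, annotation.utr3) if iv[1] > iv[0]]
    if not intervals:
        return profile
    mask = np.ones(profile.positions.shape, dtype=bool)
    removed_sites = 0
    for lo, hi in intervals:
        hi = min(hi, profile.length)
        lo = min(lo, profile.length)
        removed_sites += hi - lo
        mask &= ~((profile.positions >= lo) & (profile.positions < hi))
    new_length = profile.length - removed_sites
    if new_length <= 0:
        raise DegenerateInputError(
            f"{profile.transcript_id}: UTRs cover the whole transcript"
        )
    sub = lambda a: None if a is None else a[mask]
    return StructureProfile(
        transcript_id=profile.transcript_id,
        kind=profile.kind,
        positions=_reindex(profile.positions[mask], intervals),
        length=new_length,
        ds_reads=sub(profile.ds_reads),
        ss_reads=sub(profile.ss_reads),
        reads=sub(profile.reads),
        scores=sub(profile.scores),
    )


def _reindex(positions: np.ndarray, removed: list[tuple[int, int]]) -> np.ndarray:
    """Shift positions down by the number of removed sites preceding each."""
    shift = np.zeros(positions.shape, dtype=np.int64)
    for lo, hi in removed:
        shift += np.clip(positions - lo + 1, 0, hi - lo)
    return positions - shift


# ---------------------------------------------------------------------------
# tabular I/O

_SCORERS = {"pars": pars_content, "dms": dms_content, "predicted": predicted_content}


def score_profiles(
    profiles: Iterable[StructureProfile],
    annotations: Optional[dict[str, RegionAnnotation]] = None,
    **kwargs,
) -> pd.DataFrame:
    """Score a cohort of profiles, silently dropping excluded transcripts.

    Returns a frame with columns transcript_id, content, log_content,
    n_determined, kind.  Keyword arguments are forwarded to the kind's
    scoring function.
    """
    rows = []
    for profile in profiles:
        if annotations and profile.transcript_id in annotations:
            try:
                profile = exclude_regions(profile, annotations[profile.transcript_id])
            except DegenerateInputError:
                continue
        try:
            score = _SCORERS[profile.kind](profile, **kwargs)
        except ProfileExcluded:
            continue
        rows.append(vars(score))
    return pd.DataFrame(
        rows, columns=["transcript_id", "content", "log_content",
                       "n_determined", "kind"],
    )


def read_profiles(path, kind: ProfileKind, lengths: Optional[dict] = None):
    """Read per-nucleotide profiles from a TSV.

    Expected columns: ``transcript_id, position`` plus ``ds_reads, ss_reads``
    (pars), ``reads`` (dms) or ``score`` (predicted).  Transcript lengths
    default to max(position)+1 unless given in ``lengths``.
    """
    df = pd.read_csv(path, sep="\t")
    value_cols = {"pars": ["ds_reads", "ss_reads"], "dms": ["reads"],
                  "predicted": ["score"]}[kind]
    missing = {"transcript_id", "position", *value_cols} - set(df.columns)
    if missing:
        raise FormatError(f"profile table missing columns: {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        grp = grp.sort_values("position")
        length = None if lengths is None else lengths.get(tid)
        pos = grp["position"].to_numpy()
        if kind == "pars":
            out.append(StructureProfile.pars(
                tid, grp["ds_reads"].to_numpy(), grp["ss_reads"].to_numpy(),
                length=length, positions=pos))
        elif kind == "dms":
            out.append(StructureProfile.dms(
                tid, grp["reads"].to_numpy(), length=length, positions=pos))
        else:
            out.append(StructureProfile.predicted(
                tid, grp["score"].to_numpy(), length=length, positions=pos))
    return out


def write_profiles(profiles: Iterable[StructureProfile], path) -> None:
    """Write profiles to a TSV readable by :func:`read_profiles`."""
    frames = []
    for p in profiles:
        cols = {"transcript_id": p.transcript_id, "position": p.positions}
        if p.kind == "pars":
            cols.update(ds_reads=p.ds_reads, ss_reads=p.ss_reads)
        elif p.kind == "dms":
            cols.update(reads=p.reads)
        else:
            cols.update(score=p.scores)
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
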