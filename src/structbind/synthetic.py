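"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of input data the analysis consumes and
records the planted truth so downstream estimates can be checked against
it:

* per-nucleotide probing profiles (paired nuclease counts and chemical-
  reactivity counts) with a known per-transcript double-stranded fraction;
* CLIP peak tables whose unique-binder counts follow a known exponential
  or reciprocal law in structural content, plus sub-threshold decoy peaks;
* toy 3D protein-RNA complexes with coupled intra/inter contact densities;
* LFQ intensity matrices with planted released / kept / static proteins
  and interaction scores of known ROC AUC;
* paralog-like sequence clusters with a planted fraction of negative
  structure/binder correlations.

All draws flow from one ``numpy`` generator seeded by the config, so the
same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ComplexGeometry
from .errors import ConfigurationError, GenerationError
from .profiles import StructureProfile

#: Poisson read-rate split between the matching and the opposite nuclease:
#: a double-stranded nucleotide sends this fraction of its reads to V.
STATE_RATE = 0.9


@dataclass
class BinderLaw:
    """Planted structure-to-binder law y = f(x)."""

    alpha: float
    beta: float
    model: Literal["exponential", "reciprocal"] = "exponential"

    def __post_init__(self) -> None:
        if self.model not in ("exponential", "reciprocal"):
            raise ConfigurationError(f"unknown binder model {self.model!r}")

    def rate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "exponential":
            return np.exp(self.alpha + self.beta * x)
        denom = self.alpha + self.beta * x
        if np.any(denom <= 0):
            raise ConfigurationError("reciprocal law undefined: alpha+beta*x <= 0")
        return 1.0 / denom


@dataclass
class LfqParams:
    """Condensate-assay simulation parameters (log2 intensity scale)."""

    n_proteins: int = 1000
    frac_released: float = 0.05
    frac_kept: float = 0.03
    effect_size: float = 1.0   # log2 fold change planted in the HS condition
    noise_sd: float = 0.05     # replicate noise, log2 scale
    planted_auc: float = 0.8   # ROC AUC of interaction scores vs release
    missing_rate: float = 0.1  # per-cell missingness before planting
    #: sd of a per-protein systematic drift added to both RNA conditions of
    #: static proteins (models weak, sub-significant RNA responsiveness)
    static_drift_sd: float = 0.0
    #: how strongly a static protein's interaction score tracks |drift|;
    #: with both > 0, tightening the stringency tiers cleans the negative
    #: set and the measured AUC rises
    score_drift_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        for name in ("frac_released", "frac_kept", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_released + self.frac_kept > 1:
            raise ConfigurationError("frac_released + frac_kept must be <= 1")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ConfigurationError("noise_sd and effect_size must be >= 0")
        if not 0.5 < self.planted_auc <= 1.0:
            raise ConfigurationError("planted_auc must be in (0.5, 1]")


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    seed: int = 0
    n_transcripts: int = 500
    read_depth: float = 50.0
    length_range: tuple[int, int] = (200, 2000)
    binder_law: BinderLaw = field(
        default_factory=lambda: BinderLaw(-0.75, 0.67, "exponential")
    )
    lfq: LfqParams = field(default_factory=LfqParams)

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        if not self.read_depth > 0:
            raise ConfigurationError("read_depth must be > 0")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ConfigurationError("bad length_range")


@dataclass
class PlantedTranscript:
    """Ground truth of one synthetic transcript."""

    transcript_id: str
    length: int
    true_ds_fraction: float
    utr5_end: int
    cds_end: int
    per_nt_state: np.ndarray  # 1 = double-stranded

    @property
    def realised_ds_fraction(self) -> float:
        return float(np.mean(self.per_nt_state))


# ---------------------------------------------------------------------------
# probing profiles


def generate_structure_profiles(
    config: GeneratorConfig,
    ds_fractions: Optional[Sequence[float]] = None,
):
    """Plant per-transcript structure and draw probing read counts.

    Every nucleotide draws a double-stranded state from the transcript's
    true fraction; the paired nuclease counts are Poisson with rate
    ``depth * w`` towards the matching enzyme (w = 0.9) and the chemical
    reactivity counts are Poisson with the complementary split, so high
    reactivity marks single-stranded nucleotides.

    Returns (transcripts, pars_profiles, dms_profiles).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    if ds_fractions is None:
        ds_fractions = rng.uniform(0.0, 1.0, size=n)
    else:
        ds_fractions = np.asarray(ds_fractions, dtype=float)
        if ds_fractions.shape != (n,):
            raise ConfigurationError("ds_fractions length must equal n_transcripts")
        if np.any((ds_fractions < 0) | (ds_fractions > 1)):
            raise ConfigurationError("ds_fractions must be in [0, 1]")
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    width = len(str(n))
    transcripts, pars_profiles, dms_profiles = [], [], []
    for i in range(n):
        tid = f"tx{i:0{width}d}"
        length = int(lengths[i])
        state = (rng.random(length) < ds_fractions[i]).astype(np.int8)
        utr5_end = length // 10
        cds_end = length - length // 10
        w = np.where(state == 1, STATE_RATE, 1.0 - STATE_RATE)
        ds_reads = rng.poisson(config.read_depth * w)
        ss_reads = rng.poisson(config.read_depth * (1.0 - w))
        dms_reads = rng.poisson(config.read_depth * (1.0 - w))
        transcripts.append(PlantedTranscript(
            tid, length, float(ds_fractions[i]), utr5_end, cds_end, state
        ))
        pars_profiles.append(StructureProfile.pars(tid, ds_reads, ss_reads,
                                                   length=length))
        dms_profiles.append(StructureProfile.dms(tid, dms_reads, length=length))
    return transcripts, pars_profiles, dms_profiles


# ---------------------------------------------------------------------------
# CLIP peaks


def generate_clip_peaks(
    transcripts: Sequence[PlantedTranscript],
    binder_law: BinderLaw,
    n_rbps: int = 200,
    seed: int = 0,
    decoy_rate: float = 2.0,
    cell_lines: Sequence[str] = ("K562", "HepG2"),
) -> pd.DataFrame:
    """Peak table whose unique-binder counts follow the planted law.

    Per transcript the number of distinct above-threshold binders is
    Poisson(f(x)) with x the true double-stranded fraction; the chosen RBPs
    get peaks safely above the stringent cut-offs.  Decoy peaks (rate
    ``decoy_rate`` per transcript) fall below at least one cut-off and must
    vanish under filtering.  A ``planted`` column carries the truth.
    """
    if n_rbps < 1:
        raise ConfigurationError("n_rbps must be >= 1")
    rng = np.random.default_rng(seed)
    rbp_ids = np.array([f"RBP{i:03d}" for i in range(n_rbps)])
    rows = []
    for t in transcripts:
        lam = float(binder_law.rate(t.true_ds_fraction))
        k = int(rng.poisson(lam))
        if k > n_rbps:
            raise GenerationError(
                f"{t.transcript_id}: drew {k} binders but only {n_rbps} RBPs exist"
            )
        chosen = rng.choice(n_rbps, size=k, replace=False)
        for r in chosen:
            line = cell_lines[int(rng.integers(len(cell_lines)))]
            rows.append((t.transcript_id, rbp_ids[r], line,
                         rng.uniform(5.1, 12.0), rng.uniform(3.1, 8.0), True))
            if len(cell_lines) > 1 and rng.random() < 0.2:
                # same binder seen in a second cell line: counts stay unique
                other = [c for c in cell_lines if c != line]
                rows.append((t.transcript_id, rbp_ids[r],
                             other[int(rng.integers(len(other)))],
                             rng.uniform(5.1, 12.0), rng.uniform(3.1, 8.0), True))
        for _ in range(int(rng.poisson(decoy_rate))):
            r = int(rng.integers(n_rbps))
            mode = rng.integers(3)  # fail p, fail FE, or fail both
            neglog10_p = rng.uniform(0.0, 4.9) if mode != 1 else rng.uniform(5.1, 12.0)
            log2_fe = rng.uniform(0.0, 2.9) if mode != 0 else rng.uniform(3.1, 8.0)
            rows.append((t.transcript_id, rbp_ids[r],
                         cell_lines[int(rng.integers(len(cell_lines)))],
                         neglog10_p, log2_fe, False))
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "rbp_id", "cell_line",
                 "neglog10_p", "log2_fe", "planted"],
    )


# ---------------------------------------------------------------------------
# 3D complexes


def generate_complexes(
    n: int,
    seed: int = 0,
    contact_level: float = 1.0,
    n_rna_range: tuple[int, int] = (8, 30),
    n_protein_range: tuple[int, int] = (20, 60),
) -> list[ComplexGeometry]:
    """Toy complexes with a per-complex planted contact density.

    Phosphates and C-alphas are scattered uniformly in one cube whose
    volume is inversely proportional to a per-complex density factor, so
    intra-RNA and RNA-protein contact densities rise and fall together
    (the planted coupling behind the dataset-level correlation).
    ``contact_level=0`` spreads all atoms on a 20 Angstrom grid, leaving
    zero contacts everywhere.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if contact_level < 0:
        raise ConfigurationError("contact_level must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        n_nt = int(rng.integers(*n_rna_range, endpoint=True))
        n_aa = int(rng.integers(*n_protein_range, endpoint=True))
        n_atoms = n_nt + n_aa
        if contact_level == 0:
            side = int(np.ceil(n_atoms ** (1 / 3)))
            grid = np.stack(np.meshgrid(*[np.arange(side) * 20.0] * 3),
                            axis=-1).reshape(-1, 3)[:n_atoms]
            coords = grid
        else:
            density = rng.uniform(0.5, 1.5) * contact_level
            volume_per_atom = 350.0 / density  # ~4 neighbours within 7 A at 1.0
            cube = (n_atoms * volume_per_atom) ** (1 / 3)
            coords = rng.uniform(0.0, cube, size=(n_atoms, 3))
        out.append(ComplexGeometry(
            complex_id=f"cplx{i:04d}",
            phosphate_index=np.arange(1, n_nt + 1),
            phosphate_xyz=coords[:n_nt],
            calpha_index=np.arange(1, n_aa + 1),
            calpha_xyz=coords[n_nt:],
            length_rna=n_nt,
            length_protein=n_aa,
        ))
    return out


def write_complex_pdb(geometry: ComplexGeometry, path) -> None:
    """Write a geometry as a minimal two-chain PDB file (chains R and A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_p = len(geometry.phosphate_xyz)
    n_ca = len(geometry.calpha_xyz)
    atoms = struc.AtomArray(n_p + n_ca)
    atoms.coord = np.vstack([geometry.phosphate_xyz, geometry.calpha_xyz])
    atoms.chain_id = np.array(["R"] * n_p + ["A"] * n_ca)
    atoms.res_id = np.concatenate([geometry.phosphate_index,
                                   geometry.calpha_index])
    atoms.res_name = np.array(["U"] * n_p + ["ALA"] * n_ca)
    atoms.atom_name = np.array(["P"] * n_p + ["CA"] * n_ca)
    atoms.element = np.array(["P"] * n_p + ["C"] * n_ca)
    atoms.hetero = np.zeros(n_p + n_ca, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# LFQ condensate experiment


def generate_lfq_experiment(params: LfqParams, seed: int = 0):
    """LFQ matrix with planted released / kept / static proteins.

    Released proteins lose ``effect_size`` log2 units in the HS-RNA
    condition, kept proteins gain it; the LS-RNA condition tracks the
    background everywhere (the lowly structured RNA leaves the condensate
    unchanged).  Interaction scores are drawn from the binormal model so
    the released-vs-rest ROC AUC equals ``planted_auc`` in expectation
    (exactly separated when it is 1.0).  Cells go missing independently.

    Returns (matrix, scores, truth): a wide intensity DataFrame indexed by
    protein_id, a Series of interaction scores, and a Series of true labels.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    n = params.n_proteins
    width = len(str(n))
    ids = pd.Index([f"P{i:0{width}d}" for i in range(n)], name="protein_id")
    n_rel = int(round(params.frac_released * n))
    n_kept = int(round(params.frac_kept * n))
    labels = np.array(["static"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_rel]] = "released"
    labels[order[n_rel:n_rel + n_kept]] = "kept"
    baseline = rng.normal(25.0, 2.0, size=n)
    effect = np.where(labels == "released", -params.effect_size,
                      np.where(labels == "kept", params.effect_size, 0.0))
    drift = np.zeros(n)
    if params.static_drift_sd > 0:
        is_static = labels == "static"
        drift[is_static] = rng.normal(0, params.static_drift_sd,
                                      size=is_static.sum())
    data = {}
    for cond in ("background", "hs_rna", "ls_rna"):
        shift = effect + drift if cond == "hs_rna" else (
            drift if cond == "ls_rna" else 0.0)
        for rep in range(1, 5):
            log2_val = baseline + shift + rng.normal(0, params.noise_sd, size=n)
            vals = np.power(2.0, log2_val)
            missing = rng.random(n) < params.missing_rate
            data[f"{cond}_{rep}"] = np.where(missing, np.nan, vals)
    matrix = pd.DataFrame(data, index=ids)
    released = labels == "released"
    if params.planted_auc == 1.0:
        scores = rng.normal(0.0, 1.0, size=n)
        scores[released] = rng.uniform(10.0, 11.0, size=released.sum())
    else:
        mu = np.sqrt(2.0) * norm.ppf(params.planted_auc)
        scores = rng.normal(0.0, 1.0, size=n)
        scores[released] += mu
    scores = scores + params.score_drift_coupling * np.abs(drift)
    return (
        matrix,
        pd.Series(scores, index=ids, name="interaction_score"),
        pd.Series(labels, index=ids, name="true_label"),
    )


# ---------------------------------------------------------------------------
# paralog clusters


_BASES = np.array(list("ACGU"))


def _mutate(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hit:
        choices = [b for b in "ACGU" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return out


def generate_paralog_clusters(
    n_clusters: int,
    seed: int = 0,
    frac_negative: float = 0.64,
    members_per_cluster: int = 2,
    seq_length: int = 240,
    mutation_rate: float = 0.04,
):
    """Sequence clusters with a planted sign of structure/binder correlation.

    Each cluster derives its members from one random seed sequence by
    independent point mutation, keeping within-cluster identity above the
    85% clustering threshold while distinct clusters stay unrelated.
    Exactly ``round(frac_negative * n_clusters)`` clusters get structure
    scores and binder counts of opposite rank order (negative Pearson r);
    the rest co-vary positively.

    Returns (sequences, structure_scores, binder_counts, truth) where truth
    maps cluster ids to member lists and the planted correlation sign.
    """
    if n_clusters < 1:
        raise ConfigurationError("n_clusters must be >= 1")
    if not 0 <= frac_negative <= 1:
        raise ConfigurationError("frac_negative must be in [0, 1]")
    if members_per_cluster < 2:
        raise ConfigurationError("members_per_cluster must be >= 2")
    rng = np.random.default_rng(seed)
    n_neg = int(round(frac_negative * n_clusters))
    negative = np.zeros(n_clusters, dtype=bool)
    negative[rng.permutation(n_clusters)[:n_neg]] = True
    sequences: dict[str, str] = {}
    structure_scores: dict[str, float] = {}
    binder_counts: dict[str, int] = {}
    truth = {}
    width = len(str(n_clusters))
    for c in range(n_clusters):
        root = _BASES[rng.integers(4, size=seq_length)]
        members = []
        # reactivity-like scores: spread ranks across members
        base_score = rng.uniform(0.02, 0.10)
        score_step = rng.uniform(0.01, 0.03)
        base_count = int(rng.integers(10, 40))
        count_step = int(rng.integers(3, 12))
        for m in range(members_per_cluster):
            sid = f"c{c:0{width}d}_m{m}"
            sequences[sid] = "".join(_mutate(root, mutation_rate, rng))
            members.append(sid)
            structure_scores[sid] = base_score + m * score_step
            if negative[c]:
                binder_counts[sid] = max(base_count - m * count_step, 0)
            else:
                binder_counts[sid] = base_count + m * count_step
        truth[f"cluster{c:0{width}d}"] = {
            "members": members,
            "negative": bool(negative[c]),
        }
    return sequences, structure_scores, binder_counts, truth


# ---------------------------------------------------------------------------
# file output helpers


def write_fasta(sequences: dict, path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in sequences:
            fh.write(f">{sid}\n")
            seq = sequences[sid]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def transcripts_table(transcripts: Sequence[PlantedTranscript]) -> pd.DataFrame:
    """Truth table of a planted transcript cohort (states summarised)."""
    return pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "length": [t.length for t in transcripts],
            "true_ds_fraction": [t.true_ds_fraction for t in transcripts],
            "realised_ds_fraction": [t.realised_ds_fraction for t in transcripts],
            "utr5_end": [t.utr5_end for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
        }
    )
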