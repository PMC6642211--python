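# structbind

Analysis toolkit for **structure-driven protein interactivity of RNA**: the
observation that the amount of double-stranded (ds) structure in a transcript
tracks the number of proteins that bind it. The package implements the full
analysis chain around that relationship — from per-nucleotide structure
probing counts to condensate-remodelling proteomics — and ships a
synthetic-data generator with planted ground truth so every stage can be
exercised and validated without external downloads.

It is written for computational RNA biologists who have (or simulate)
structure-probing data, CLIP peak tables, protein–RNA complex coordinates, or
label-free quantification (LFQ) matrices and want the corresponding
transcript-level statistics.

## What it computes

**Structural content** (`structbind.profiles`). For paired nuclease probing
(V = double-strand-specific reads, S = single-strand-specific reads), the
content of a transcript of length *l* is the fraction of nucleotides called
double-stranded by a stepwise rule:

```
content = (1/l) * sum_i  theta( log10( V(i) / S(i) ) ),   theta(x) = 1 if x > 0 else 0
```

with UTR masking, a chemical-reactivity variant (reads normalised to the
transcript maximum and averaged; higher = *less* structured) and a
predicted-score variant (fraction of positive per-nucleotide scores). The
transcript-level log score uses the natural log: a score of −1.3 corresponds
to ~26% ds content, −2.8 to ~6%.

**Binder counts** (`structbind.clip`). CLIP peaks are filtered at stringent
cut-offs (−log10 p > 5 and log2 fold enrichment > 3, both strict), unique
RNA-binding proteins (RBPs) are counted per transcript with cell lines merged
by union, RBP structure preferences are called against a transcriptome
background (Mann–Whitney, p ≤ 0.01), and binder-set overlaps get an empirical
p-value from 1000 random draws.

**Structure→binder laws** (`structbind.regression`,
`structbind.interactivity`). Two functional forms relate structural content
*x* to binder count *y*: `y = exp(α + βx)` and `y = 1/(α + βx)`, fitted by
damped Gauss–Newton least squares (scikit-learn estimator API:
`ExponentialRegression`, `ReciprocalRegression`). Transcripts are stratified
into equal-size high-structure/low-structure (HS/LS) sets and compared by KS
test; near-identical paralogs are clustered greedily at 85% global-alignment
identity and each cluster's structure/binder Pearson correlation is reported.

**3D contact statistics** (`structbind.contacts`). From protein–RNA complex
coordinates: internal contacts = P–P pairs of distinct nucleotides under 7 Å,
external contacts = P–Cα pairs under 7 Å, normalised as
`log2((1+n_int)/len_RNA²)` and `log2((1+n_ext)/(len_RNA·len_prot))`, plus the
dataset-level Pearson correlation between the two scores.

**Condensate assay** (`structbind.condensate`). For an LFQ matrix
(background / HS-RNA / LS-RNA × 4 replicates): quantifiability filter (≥3
valid values in some condition), Welch t-test per protein on log2
intensities, released/kept/static classification at −log10 p > 1.3, nested
stringency tiers (|log2 ratio| < 0.15 / 0.30 / 1 among non-significant
proteins), and a rank-sum ROC AUC of interaction scores against release
labels.

**Protein properties** (`structbind.properties`). Mean Grantham polarity,
Chou–Fasman α-helix propensity or Kyte–Doolittle hydropathy per protein, and
KS comparisons between protein sets (e.g. released vs static).

## Worked example

Generate a synthetic cohort whose binder counts follow a planted exponential
law in the true ds fraction, then run the analysis end to end:

```python
import numpy as np
from structbind import synthetic, clip, profiles
from structbind.interactivity import fit_exponential, ks_compare, stratify

config = synthetic.GeneratorConfig(seed=42, n_transcripts=1000, read_depth=50.0)
transcripts, pars_profiles, _ = synthetic.generate_structure_profiles(config)
scores = profiles.score_profiles(pars_profiles).set_index("transcript_id")["content"]

law = synthetic.BinderLaw(alpha=-0.75, beta=0.67)
peaks = synthetic.generate_clip_peaks(transcripts, law, n_rbps=100, seed=42)
kept = clip.filter_peaks(peaks)
counts = clip.count_binders(kept, transcripts=scores.index).set_index("transcript_id")["n_binders"]

sets = stratify(scores.to_dict(), fraction=0.2)
hs, ls = counts[list(sets.hs_ids)], counts[list(sets.ls_ids)]
d, p = ks_compare(hs, ls)
fit = fit_exponential(scores[counts.index], counts)
print(f"retained {len(kept)}/{len(peaks)} peaks after stringent filtering")
print(f"HS mean binders {hs.mean():.2f} vs LS {ls.mean():.2f} (KS D={d:.2f}, p={p:.2e})")
print(f"fitted law: y = exp({fit.alpha:.3f} + {fit.beta:.3f} x), rss={fit.rss:.1f}, n={fit.n}")
```

which prints:

```
retained 852/2894 peaks after stringent filtering
HS mean binders 0.92 vs LS 0.44 (KS D=0.24, p=2.43e-05)
fitted law: y = exp(-0.848 + 0.912 x), rss=662.5, n=1000
```

The decoy peaks vanish under the stringent cut-offs, the highly structured
quintile binds about twice as many proteins as the lowly structured one, and
the fitted coefficients sit near the planted (−0.75, 0.67) — not exactly on
them, because the regression here uses the *measured* content of each
transcript rather than its true planted fraction.

The same stages are scriptable from the shell via the `structbind` console
command (`structbind simulate …`, `structbind score …`, `structbind clip …`,
`structbind contacts score …`, `structbind condensate …`,
`structbind properties …`); see `structbind --help`.

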