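# Methods

This note documents the models, conventions and numerical choices behind
`structbind`, and what the synthetic study conditions do and do not show
about real data.

## Structural content scores

**Stepwise nuclease score.** A nucleotide is called double-stranded when
`log10(V/S) > 0`, i.e. strictly more double-strand-specific than
single-strand-specific reads. Boundary conventions: `V = S` (including both
zero after pseudocounting) contributes 0, since only values *above* zero
indicate pairing; `S = 0, V > 0` is the ratio's +∞ limit and contributes 1;
`V = 0` contributes 0. No pseudocount is added by default (a `pseudocount`
flag exists; because it shifts numerator and denominator equally it never
changes a call, only the definition of "determined" stays read-based).

**The denominator l.** Transcripts whose nucleotides are all undetermined
(`V + S = 0` everywhere) are discarded. By default the score normalises by
the number of *determined* nucleotides rather than the full transcript
length: normalising by full length would deflate the content of sparsely
covered transcripts purely as a function of sequencing depth, which would
leak coverage into a structure statistic. The full-length variant is
available via `denominator="full"` for strict length normalisation.

**Chemical-reactivity score.** Reads are divided by the transcript's maximum
and averaged over the positions present in the input (zero-read positions
present in the table count toward the average; they carry the information
that the position was probed but unreactive). Transcripts whose
nonzero-read positions cover less than 10% of the sequence length are
excluded, as are transcripts with no reads at all. The scale is inverted
relative to the nuclease score — high reactivity means unpaired — so
preference analyses negate it to keep a higher-is-more-structured
convention.

**Log scale.** The transcript-level log score is the natural log of the
content fraction: exp(−1.3) ≈ 27% and exp(−2.8) ≈ 6%, matching the
score↔percentage pairs quoted for the canonical HS (HSP70 mRNA) and LS
(BRaf mRNA) transcripts; a base-10 reading would not.

**UTR masking** removes annotated 5′/3′ UTR intervals and renumbers the
retained span, so both denominator choices refer to the coding span only.

## CLIP catalogue

Filtering is strict (`>`, not `≥`) on both −log10 p and log2 fold
enrichment, defaults 5 and 3. The enrichment threshold is read as
`log2(FE) > 3`: selecting by a *negative* log2 enrichment above 3 would
keep depleted peaks, the opposite of a stringent top-of-distribution
filter. Binder counts are unique RBP identities per transcript, cell lines
merged by union, so replicated detection never inflates a count.

Structure preference uses a two-sided Mann–Whitney U test (the package's
choice; a KS option exists) with a median direction rule at p ≤ 0.01.
The empirical overlap p-value uses the add-one estimator
`(1 + #{draws ≥ observed}) / (n + 1)`, one-sided for enrichment, so finite
sampling can never report p = 0.

## Structure→binder laws

Both laws are fitted by unweighted least squares on the original y scale —
the forms are published without an error model, so no weighting is assumed.
The initial point comes from ordinary regression of a linearised response
(ln(y+1) or 1/y on x) and is refined by damped Gauss–Newton: full steps are
halved until the RSS decreases, and iteration stops when the gradient norm
falls below `tol · (1 + RSS)` or the RSS improvement stalls below machine
scale. The relative criterion matters: with thousands of noisy points the
absolute gradient at the optimum sits far above any fixed tiny threshold.
On noiseless generated data both fitters recover the generating coefficients
to ≤ 1e−6 (exponential) / 1e−4 (reciprocal), and the RSS at the solution is
never worse than at the initialiser. A Poisson-likelihood option
(`loss="poisson"`, a log-link GLM via statsmodels) is the natural choice for
count responses; least squares remains the default because the published
form is a plain curve fit. The reciprocal fit additionally requires
`α + βx > 0` over the data range at the solution and raises a diagnostic
error (carrying the last iterate) otherwise.

HS/LS stratification ranks ids once by (score desc, id asc); HS is the head
and LS the tail of the ranking, giving equal-size, disjoint sets for any
fraction ≤ 0.5 with a deterministic tie rule.

## Sequence clustering

Greedy representative clustering: sequences in length-descending (then id)
order either join the first cluster whose *founding* sequence they match at
≥ 85% identity or found a new cluster. Identity is matches / alignment
columns under global alignment with match 1, mismatch 0, gap open −1,
extend −0.5 (Biopython's pairwise aligner). This is deliberately a
consistent ≥-threshold criterion, not a re-implementation of CD-HIT's
word-filtered identity; the threshold is exposed. Per-cluster Pearson r of
(structure score, binder count) uses only members with both values;
clusters reduced below two members are dropped. For two-point clusters the
correlation is the sign of the slope (±1), reported without a p-value.

## Contact statistics

Contacts are counted strictly below 7 Å: internal = unordered P–P pairs of
distinct nucleotides (sequence-adjacent pairs included — adjacent
phosphates are typically within 7 Å and no exclusion is specified by the
definition), external = P–Cα cross pairs. A k-d tree accelerates the
neighbour search; equality at the cutoff is filtered explicitly so the
strict inequality survives the tree's inclusive radius query, and the
counts are verified against an O(n²) double loop in the tests. An
`ordered_internal` flag doubles internal counts for the
both-directions reading. Scores are `log2((1+n)/len²)` and
`log2((1+n)/(len_RNA·len_prot))`; the +1 keeps zero-contact complexes
finite. Structure files are read with biotite (first model,
highest-occupancy altloc, hetero/solvent skipped); every RNA×protein chain
pair yields one record, chain length = residues observed in the chain, so
residues missing their P/Cα atom still count toward length. A resolution
filter is metadata-level and not applied to synthetic fixtures.

## Condensate assay

Intensities are log2-transformed before testing (LFQ intensities are
approximately log-normal; a raw-scale flag exists). The differential test
is Welch's t-test by default — the safer choice when only "two-sample
t-test" is specified — with Student's behind a flag. Missing values are not
imputed; a side with fewer than two valid values makes the protein
untestable ("unquantified"). Zero-variance-both-sides cases degenerate to
p = 1 (equal means) or p → 0 (unequal) and are flagged. The released/kept
threshold −log10 p > 1.3 is p < 0.05. Tier bounds (0.15 / 0.30 / 1) are
applied to the log2 ratio — the printed thresholds' base is not stated, so
base 2 is assumed and configurable; tiers require non-significance and the
bound for *both* RNA conditions and nest by construction. The ROC AUC is
the midrank Mann–Whitney form (ties credited 0.5), checked against
scikit-learn in the tests.

## Protein properties

Property scores are unweighted means over standard residues; ambiguity
codes and rare translated residues (X, B, Z, U, O) are skipped and counted.
The packaged tables are the canonical literature scales — Grantham (1974)
polarity, Chou–Fasman Pα helix propensities, Kyte–Doolittle (1982)
hydropathy — stored in a versioned JSON whose SHA-256 is verified at load.
Set comparisons delegate to the two-sample KS test. The full multi-scale
enrichment machinery used in large RBP surveys is out of scope; per-scale
set comparison is the supported reduction.

## Synthetic study conditions

The generator defines the conditions under which the pipeline is validated:

* **Probing profiles**: per-nucleotide states are Bernoulli(true ds
  fraction); read counts are Poisson with a 0.9/0.1 rate split between the
  matching and opposite channel at a mean depth of 50 reads/nt over cohorts
  of 500 transcripts (200–2000 nt) — depths and sizes at which the content
  estimator is effectively noiseless. UTRs occupy the outer 10% of each
  transcript.
* **Peaks**: distinct-RBP binder counts are Poisson(f(x)) in the *true*
  content x — Poisson is this package's choice of count noise, as no
  distributional form is published for scatter around the laws — with
  above-threshold statistics for planted peaks, sub-threshold decoys
  (~2/transcript) and occasional second-cell-line duplicates.
* **Complexes**: all atoms of a complex share one cube whose volume is set
  by a per-complex density factor, coupling intra- and inter-molecular
  contact density by construction (the planted analogue of the observed
  internal/external correlation); contact_level scales the density, 0 is a
  contacts-free grid.
* **LFQ**: log2 intensities N(25, 2) baseline, replicate noise sd 0.05,
  released/kept effects ∓1 log2 unit in the HS condition only, 10% missing
  cells, and interaction scores from the binormal model at a planted AUC
  (exactly separated at AUC = 1). Optional static-protein drift coupled to
  the score reproduces the stringency-tier AUC improvement.
* **Paralogs**: clusters of point-mutated copies (4% substitution rate,
  240 nt default — short enough that the 100-cluster analysis runs in
  seconds, long enough that inter-cluster identity stays far below 85%);
  the negative-correlation label is planted *exactly* on
  round(frac·n) clusters by monotone score/count assignment, so recovery
  tests measure the clustering and correlation path, not planting noise.

What passing these conditions does **not** show: real probing data have
coverage biases, transcript-abundance confounding and correlated noise that
Poisson-per-nucleotide sampling lacks; real CLIP counts reflect expression
and crosslinking efficiency, not only structure; real complexes are
polymers, not uniform point clouds; real LFQ missingness is
intensity-dependent (left-censored), not uniform. The tests demonstrate
correctness of the statistics and recoverability of planted signal, not
robustness to those real-data artefacts.

## Known limitations

* The nuclease content score ignores read-count magnitude beyond the V/S
  sign, by design of the stepwise rule.
* Greedy clustering is order-dependent (as is its reference scheme);
  results are deterministic but can differ from optimal clustering.
* The empirical overlap test is sampling-based; its resolution is bounded
  by 1/(n_samples+1).
* `parse_structures` recognises RNA chains by standard ribonucleotide
  residue names; heavily modified RNA chains would need the residue set
  extended.
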