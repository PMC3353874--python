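# Methods

## The AMT-tag analysis model

The pipeline implements accurate-mass-and-time (AMT) tag label-free
quantification. MS/MS identifications from pooled, fractionated samples
define a library of tags — peptide sequence, theoretical neutral
monoisotopic mass, and consensus normalized elution time (NET, scaled to
[0, 1]) — and single-stage LC-MS runs of individual samples are quantified
by assigning each detected feature (monoisotopic mass, NET, intensity) to
the nearest tag inside a mass/NET tolerance window. The identity carried by
the tag turns intensity into peptide-level abundance without re-sequencing
every sample.

Key conventions, all configurable, with their defaults:

| parameter | default | role |
|---|---|---|
| probability cutoff | 0.5 | minimum posterior for an identification |
| Xcorr thresholds | 1.9 / 2.2 / 3.5 | single-spectrum cut by charge 1+/2+/≥3+ |
| relaxed Xcorr | 1.9 | peptides seen in ≥ 2 MS/MS spectra |
| ppm tolerance | ±10 ppm | mass window for feature→tag matching |
| NET tolerance | ±0.025 | elution window (no literature value; chosen wide enough for the simulator's NET noise, narrow enough to suppress collisions) |
| min peptides | 2 | peptides required to quantify a protein |
| min presence | 25% | samples a peptide must be observed in to enter rollup |
| screen filter | \|r\| ≥ 0.3, p ≤ 0.05 | correlate selection |
| min pairs | 10 | pairwise-complete observations for any correlation |
| RNA floor | 39 copies/mL | below-detection value before log10 |
| NFL floor/limit | 124 / 125 ng/L | older-assay lower limit convention |

Decisions the sources leave open, fixed here and declared so tests are
exact:

- **FDR** is decoys/targets on the filtered sets (separate target and decoy
  searches), capped at 1.
- **NET normalization** is a per-run min–max affine map; an optional
  second pass regresses run times onto library NETs for drifted runs.
  Chromatographic warping is out of scope.
- **Consensus NET** is the median over a peptide's observations (robust to
  outlier runs).
- **Match tie-breaking** minimizes the scaled squared distance
  (ppm/ppm_tol)² + (ΔNET/net_tol)²; exact ties go to the lower tag mass.
  Note that because ppm error is relative to each candidate's own mass,
  candidates placed symmetrically around a feature are not tied.
- **σ̂ ppm** is MAD × 1.4826 rather than a plain SD: the tolerance window
  truncates the tails and false matches contaminate the extremes, both of
  which bias the plain estimator (the tests plant 1% contamination to
  verify this).
- **Duplicate runs** are averaged in log2 space (geometric mean of raw
  intensities); a peptide observed in only one duplicate uses that run.
- **Shared peptides** (mapping to > 1 protein) are excluded from rollup by
  default to avoid double counting; a razor mode assigns them to the
  mapped protein with the most unique peptides.
- **R-rollup reference** is the peptide observed in the most samples, ties
  to the higher median abundance, then lexicographic; every other peptide
  is shifted by the median of (reference − peptide) over shared samples,
  and the protein profile is the per-sample median of shifted peptides.
  This makes the protein profile exact (up to one additive constant per
  protein) when peptide profiles are parallel, which the noiseless
  recovery test exploits.
- **Missing values stay missing** — never imputed, never zero; all
  statistics use pairwise-complete observations with the min-pairs floor.
- **No multiple-testing correction in the screen** by default (the
  selection rule is a raw p plus a hard |r| magnitude cut); a
  Benjamini–Hochberg helper is provided for users who want it.
- **Clustering** is average linkage on d = 1 − r. Flat clusters come from
  cutting the dendrogram at a requested count; "cluster 1–5"-style visual
  groupings are approximated by `protein_cluster_k` (default 5).
- **Enrichment universe** is the set of quantified proteins, not a genome:
  enrichment is relative to what the experiment could detect.

## The synthetic cohort

`SimulationConfig` defaults describe the emulated study: 12 uninfected
subjects with one lumbar puncture each, 14 infected subjects with 79
samples total (4–7 longitudinal time points starting at cART initiation,
week 0), every sample run in duplicate. The true log2 abundance of protein
p in sample s is

    x[p,s] = baseline_p + group_p·I(infected) + subject_{p,subj(s)}
             + Σ_b λ_{p,b}·z_b(s) + ε[p,s]

with baseline ~ N(20, 1.5²) (log2 of typical MS intensities), group effect
SD 0.8 (separates infected from uninfected proteomes), subject signature
SD 0.3 (individual proteome "fingerprints", making within-subject sample
correlations exceed between-subject ones), and residual SD 0.5. Biomarker
trajectories decline after treatment start — RNA log-linearly to its
39 copies/mL floor, neopterin and NFL exponentially toward uninfected-like
levels — with one planted non-responder subject whose markers stay flat.

Couplings: `n_neopterin_coupled` / `n_nfl_coupled` / `n_rna_coupled`
proteins (default 40/0/0 of 300; `n_overlap` proteins couple to both
neopterin and NFL) load onto the z-scored biomarker with
λ = m·σ_noise/√(1 − m²), σ_noise² = subject SD² + residual SD², so the
population correlation between a coupled protein and its biomarker over
infected samples is the configured `loading_magnitude` (default 0.6), with
random sign. Emission adds measurement error: mass × (1 + e/10⁶),
e ~ N(0, 2.0 ppm); NET + N(0, 0.01) clipped to [0, 1]; independent peptide
dropout at 15%; per-peptide log2 ionization offsets ~ N(0, 1). The
identification table adds an equal number of reversed-sequence decoys with
Xcorr drawn from a null shifted 0.8 below the charge threshold, so the
filter and FDR estimator are genuinely exercised.

True NETs are a deterministic hash of the peptide sequence mapped to
[0.05, 0.95] — reproducible, and collision behavior is testable. Tryptic
digestion uses the standard K/R-not-before-P rule; peptides of 6–30
residues are retained as observable.

What the simulator does **not** emulate: chromatographic peak shapes,
isotope envelopes, charge-state deconvolution, intensity-dependent
(non-random) missingness, inter-sample normalization drift, or correlated
peptide-level noise. Tests passing on this cohort therefore demonstrate
correctness of the statistical machinery and recovery of planted
structure, not robustness to every artifact of real LC-MS data.

Because the simulated biomarkers are themselves correlated (they all
respond to treatment), proteins coupled to one biomarker genuinely
correlate with the others; screen "false positives" against planted
memberships are dominated by this cross-signal. Calibration claims
(selection ≤ 5% at the joint filter) are therefore checked on cohorts
whose null proteins are coupled to nothing, and on fully independent
Gaussian data.

## Problem sizes and numerics

The default test and demonstration sizes — 300-protein screening cohorts,
a 120-protein end-to-end demo (~290k features over 182 runs), 10,000-rep
calibration checks, an exhaustive hypergeometric comparison to N = 60 —
were chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo error far below the asserted tolerances. Determinism
is end-to-end: all randomness flows from `numpy.random.default_rng`
seeded from the config, and the summary JSON is written with sorted keys
and no timestamps, so identical config + seed reproduces byte-identical
output.

Degenerate inputs are rejected early with messages (empty sequences,
invalid residues with position, zero-variance biomarkers, degenerate
calibration pairs, infeasible planted counts); zero-variance proteins are
flagged and excluded from screens rather than producing NaN correlations
silently.

## Known limitations

- NET alignment is a declared simplification (min–max or one linear
  regression pass); real gradient drift is nonlinear.
- Protein inference is by peptide-mapping rollup only — no probabilistic
  protein grouping; degenerate peptides are dropped or razor-assigned.
- The screen's per-protein tests are marginal; no attempt is made to model
  the within-subject correlation of longitudinal samples (a fixed-effects
  simplification shared with the analysis it implements).
- Enrichment assumes exchangeable proteins within the universe; no
  ontology structure or set overlap correction.
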