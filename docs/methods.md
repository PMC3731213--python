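# Methods

## Occupancy model

Candidate sites of each motif are found on both strands of a window; a site's
strength enters only through its relative affinity `exp(LLR − LLR_max)`, so
the consensus site of a motif has weight γ and every other site a fraction of
it.  A configuration is any subset of candidate sites whose intervals do not
overlap (two opposite-strand matches at one position are distinct, mutually
overlapping candidates, so their exclusion falls out of overlap handling).
Its weight is the product of bound-site weights times one interaction factor
ω per *adjacent* bound primary–secondary pair whose gap (end of the left
site to start of the right site, in bp) is between 0 and d_T.  Restricting ω
to adjacent bound pairs — no intervening bound site — is what makes the
last-bound-site dynamic program exact, and reflects that the model describes
one pairwise contact, not a chain of simultaneous contacts; homotypic
neighbors carry no interaction term.  Multiple interacting pairs in one
configuration multiply their ω factors.

The DP scans sites in coordinate order, maintaining per-last-bound-site
accumulators of (ΣW, ΣW·N_primary).  Its cost is quadratic in the number of
candidate sites in a window, which is at most a few dozen at the default
scanning threshold; accumulators are rescaled in place when they exceed
1e250, so the OCC ratio stays exact at γ up to 1e5 without log-space
arithmetic.  A brute-force enumerator over all non-overlapping subsets
(feasible to ~25 sites) is kept as an independent oracle and agrees with the
DP to 1e-9 relative tolerance on randomized instances in every mode.

## Scanning thresholds

Two site-inclusion criteria exist because they serve different purposes:

* **Occupancy model**: relative affinity ≥ 0.01 of consensus (configurable).
  The occupancy prediction is fairly insensitive to weaker sites (their q is
  tiny at any γ in bounds), and this floor keeps the DP small while retaining
  medium-strength sites.
* **Spacing-bias tests**: per-site p-value ≤ e⁻⁷ under the background model,
  the conventional stringency for site-level analyses.  The null score
  distribution is computed by exact dynamic programming over the PWM score
  grid (step 1e-4 nats, with a one-step-per-position safety margin so
  discretization can only tighten, never loosen, the threshold).

LLRs are in natural log (the occupancy formula exponentiates them);
information content is reported in bits.  PWMs get a pseudocount floor of
1e-3 (renormalized) at load so no log-ratio is infinite.  Sites overlapping
ambiguous bases are excluded.  Coordinates are 0-based half-open throughout.

## Fitting and evaluation

γ is constrained to [1, 10⁴] and searched on a log10 grid of step 0.5; ω on
a log10 grid of step 0.5 within [1, 100] (cooperative) or [0.01, 1]
(antagonistic); competition fixes ω = 1.  The training objective is the
Pearson correlation between predictions and ChIP scores — scale-free, which
matters because the model predicts expected bound-site counts while ChIP
scores are in arbitrary units with no stated calibration.  The best grid
point is polished by a bounded coordinate pattern search (half-grid initial
step, step halving when stuck, objective tolerance 1e-3, ~60 evaluations) —
a deliberately simple derivative-free local search over at most three
parameters.

Evaluation is 4-fold cross-validation, stratified so each test fold holds
equal shares of peaks and non-peaks; out-of-fold predictions are concatenated
before computing any reported correlation, so two-motif models pay for their
extra parameters.  A fit is flagged inconsistent when the per-fold primary
log10 γ values span more than 2 decades (the surrogate for discarding a
dataset whose folds disagree).  Predictions that are constant over a window
set define a correlation of 0 inside the optimizer (no linear information);
user-facing correlation functions raise on constant input instead.

## Significance of a secondary motif

ΔCC = CC(M1+M2) − CC(M1) and ΔCC′ = CC(M1+M2) − |CC(M2)| (absolute value:
a strongly *anti*-correlated secondary-only model is still informative on its
own and must be beaten).  The ΔCC ≥ 0.04 screen runs before any shuffling —
it exists to avoid spending 100 refits on hopeless candidates — so screened-
out candidates carry no p-value and are never significant.  The empirical
p-value counts shuffled-motif ΔCC values ≥ the observed one (ties count
against the candidate, the conservative direction), at resolution 1/100; an
empirical zero is reported as "<0.01".  Row and column permutation of the
PWM preserves its information content exactly under the uniform background,
so the null motifs are matched in information while losing the specific
base-order signal.  The modified Z-score is the Iglewicz–Hoaglin robust
outlier statistic, 0.6745·(x − median)/MAD over the ΔCC of all candidates
tested on the dataset, falling back to 1.253314 times the mean absolute
deviation about the median when the MAD vanishes.  All four conditions
(ΔCC ≥ 0.04, ΔCC′ ≥ 0.04, p ≤ 0.05, Z ≥ 3) must hold jointly.

One open choice: the robust-Z formulation and the tail convention of the
shuffle test are fixed here by the outlier-detection reading (median/MAD,
one-sided enrichment); other conventions would shift borderline calls only.

## Accessibility

Accessibility tracks are smoothed exactly like ChIP (raw positions mapped to
the nearest 50 bp grid point, 500 bp window means); a window is "accessible"
iff its score reaches the stage-specific 90th percentile across the dataset
(ties at the threshold included; windows with no track coverage are flagged
inaccessible).  Two uses: hard filtering (predictions zeroed outside
accessible windows) and the semi-partial correlation
SPCC = (r_xy − r_xz·r_yz)/√(1 − r_yz²), the correlation between predictions
and the ChIP residual after regressing out accessibility.  A secondary
influence that is significant in ΔCC but shows ΔSPCC < 0.04 is classified
accessibility-mediated (pioneer-like); ΔSPCC ≥ 0.04 marks an
accessibility-independent mechanism.

## Spacing bias

Adjacent heterotypic site pairs (consecutive sites in coordinate order
belonging to different motifs, strand ignored) are binned by gap into
[1–2], [2–3], …, [29–30] bp.  The background redraws each segment's site
locations uniformly without overlap — site counts, identities and lengths
preserved per segment; placement is rejection-sampled with 1000 attempts —
and pools 10 randomizations.  Each bin gets a one-tailed (enrichment)
Fisher's exact test of observed vs background in-bin counts; the reported
statistic is the minimum p-value across bins and its bin, with no
multiplicity correction (by design: the scan is a descriptive localizer, and
the minimum across 29 strongly dependent bins is reported as such).  Tests
run separately on the top-scoring peaks and on non-peaks.

## Dataset construction

Raw track scores are mapped to the nearest multiple of 50; each 500 bp
window on the 50 bp grid scores the mean of mapped scores inside it (0 when
none map, keeping the genome-wide grid dense).  Peaks are selected greedily
by descending score (ties by genomic coordinate), each selection masking
overlapping windows; non-peaks are drawn uniformly without replacement
(seeded) from the remaining windows, rejecting any ≥1 bp exon overlap, peak
overlap, or mutual overlap.  No exclusion buffer is placed around peaks.  An
alternate negative mode draws non-peaks from a supplied pool of other
factors' peaks.  Candidate secondary motifs are ranked by TF expression:
log1p levels are z-scored within each stage ("stage-normalized"), averaged
across the dataset's stages, and the top fraction of TFs with motifs is
tested; heterodimer-complex motifs (catalog names containing `::`) are
excluded.  Full-scale datasets are 1000 peaks + 1000 non-peaks;
validation-scale runs use 200 + 200.

## Synthetic data: what it emulates, and what it does not

The generator produces i.i.d. background sequence at GC 0.41 (fly-like) in
500 bp windows, plants primary sites (one per bound window by default,
sampled base-by-base from the motif's own columns so site strengths vary
realistically), co-plants a secondary site near the primary in 70% of bound
windows (gap uniform within d_T, or a fixed gap for spacing studies, or a
4 bp overlap for competition), computes each window's true occupancy under
the generating model, and adds Gaussian noise (sd 0.1 on the occupancy
scale).  Datasets are then assembled the same way real ones are: top scores
become peaks, negatives are sampled from the remainder.

The standard conditions per mode are: cooperative γ = (10, 31.6), ω = 10;
antagonistic γ = (31.6, 100), ω = 0.02; competition γ = (10, 316) with the
competitor's leading columns sharpened to match the primary consensus tail
so intact sites can overlap (both on the plus strand).  The asymmetric
concentrations encode an abundant partner or competitor; they were chosen,
together with the planting rates and noise level, so that each interaction
mode contributes a share of signal variance that is clearly detectable at
the 200+200-window validation scale — sampled sites average only a few
percent of consensus affinity, so a competitor at equal concentration steals
almost no occupancy and antagonism at ω = 0.1 is nearly invisible behind
peak/non-peak separation.  Two accessibility scenarios are synthesizable:
"mediated" (the secondary acts only as a latent pioneer raising
accessibility, which gates the ChIP signal; the binding model itself is
single-motif) and "correlated" (accessibility tracks primary occupancy plus
noise, independent of the interaction).

What passing tests on this generator show: the scanning, fitting,
cross-validation and significance machinery recovers planted effects of the
kind the model family describes, with correct mode, distance range and
mechanism classification, and rejects information-matched decoys.  What they
do not show: that effects of this size or clarity exist in real ChIP data —
real signal is far noisier (correlations of 0.1–0.7 rather than ~0.9),
motifs are imperfect, site planting is not independent of background
composition, accessibility is not a clean gate, and TF concentrations are
unknown.  The generator also does not emulate read-level artifacts, mapping
bias, or nucleosome-sequence preferences.

## Numerical and procedural choices

* All randomness flows from explicit integer seeds through named substreams;
  pipeline reruns with the same config are byte-identical.
* Empirical p-values of zero print as "<1/n_shuffles"; tables print two
  decimals in the conventional layout (dataset, M2, CC(M1), CC(M2),
  CC(M1+M2), ImprOverM1, ImprOverM2, P-value, Z-score).
* Tie-breaks are documented and deterministic: equal-score windows by
  genomic coordinate; equal-CC motif candidates by input order.
* Degenerate inputs fail loudly: constant training scores, single-class AUC
  input, collinear accessibility in the semi-partial correlation, a pool
  without spread in the robust Z.

## Known limitations

* One secondary motif at a time, heterotypic interactions only; no homotypic
  cooperativity, no joint model over many TFs, and no additive
  "indirect binding" model.
* The interaction applies between adjacent bound pairs only; a secondary
  site can therefore be "shielded" by an intervening bound site, which is a
  modeling choice rather than established biochemistry.
* Expression-based candidate ranking assumes whole-embryo RNA levels proxy
  nuclear protein concentration.
* The spacing scan reports an uncorrected minimum over bins and is meant as
  a descriptive follow-up to an already-significant interaction, not a
  stand-alone discovery test.
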