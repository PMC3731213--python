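# thermoccupancy

Thermodynamic modeling of transcription-factor (TF) occupancy from sequence,
and statistical detection of *secondary* TF motifs that shape a primary TF's
ChIP profile — cooperatively, antagonistically, or by competing for
overlapping binding sites.

## Who this is for

Regulatory genomicists who have a ChIP signal track for one TF (the
"primary"), a catalog of binding motifs (PWMs), and optionally DNA
accessibility and TF expression data, and who want to ask: *how much of this
TF's binding profile is explained by its own motif, and which other expressed
TFs measurably raise or lower its occupancy — and by what mechanism?*

## The model

A 500 bp window contains candidate binding sites found by scanning PWMs.  A
molecular configuration σ picks a subset of non-overlapping sites to be
simultaneously bound; its Boltzmann weight is

    W(σ) = ∏_{S ∈ σ} q(S) · ∏_{interacting pairs in σ} ω,

where each bound site contributes

    q(S) = γ_TF · exp(LLR(S) − LLR(S_max)),

with γ_TF = K(S_max)·[TF], the product of the consensus-site equilibrium
constant and the TF concentration (the model's one free parameter per motif,
constrained to [1, 10⁴]), and LLR the log-likelihood-ratio score of the site
under the PWM versus background.  When a bound primary site and a bound
secondary site are adjacent and separated by at most a distance threshold
d_T (30 bp "short-range", 150 bp "long-range"), the weight is multiplied by
the interaction term ω: ω > 1 is cooperative, ω < 1 antagonistic, ω = 1
leaves only competition through site overlap.  The predicted occupancy of
the primary TF is the thermodynamic average of its bound-site count,

    OCC = Σ_σ N(σ) W(σ) / Σ_σ W(σ),

computed exactly by a dynamic program over sites in coordinate order (an
explicit configuration enumerator serves as its oracle in the tests).

A candidate secondary motif M2 is judged by the gain in 4-fold
cross-validated Pearson correlation with the ChIP scores over the
primary-only baseline, ΔCC = CC(M1+M2) − CC(M1).  It is called a significant
influence only if ΔCC ≥ 0.04, ΔCC′ = CC(M1+M2) − |CC(M2)| ≥ 0.04, an
empirical p-value ≤ 0.05 against 100 information-content-preserving shuffles
of M2, and a median/MAD ("modified") Z-score ≥ 3 against the ΔCC of all
tested candidates.  Semi-partial correlation against accessibility separates
accessibility-mediated from accessibility-independent influences, and
one-tailed Fisher tests on inter-site spacings flag preferred geometries
suggestive of direct physical interaction.

## Worked example

Simulate a dataset with a planted long-range cooperative partner (ω = 10,
d_T = 150 bp), then ask whether the analysis recovers it against shuffled
decoys:

```python
from thermoccupancy.synthetic_data import TruthModel, simulate_dataset
from thermoccupancy.training import CVFolds
from thermoccupancy.evaluation import assess_secondary_influence
from thermoccupancy.motifs import shuffle_pwm
from thermoccupancy.pipeline import influence_table

truth = TruthModel.cooperative(seed=7, d_T=150)
dataset, manifest = simulate_dataset(truth, n_peaks=200, n_nonpeaks=200, seed=7)
folds = CVFolds.stratified(dataset.labels, seed=7)
decoys = [shuffle_pwm(truth.secondary, k) for k in range(8)]
result = assess_secondary_influence(
    dataset, truth.primary, truth.secondary, mode="cooperative", d_T=150,
    n_shuffles=100, candidate_pool=decoys, rng_seed=7, folds=folds,
)
print(influence_table([result], n_shuffles=100).to_string(index=False))
```

Output:

```
                dataset           M2        mode  d_T  CC(M1)  CC(M2)  CC(M1+M2)  ImprOverM1  ImprOverM2 P-value  Z-score  significant
SYNTH_cooperative_dt150 pwm_ae6ffa92 cooperative  150  0.8997  0.5022     0.9887       0.089      0.4866   <0.01    99.67         True
```

Reading the row: the primary motif alone explains the ChIP scores with
CC = 0.90; adding the planted partner in cooperative mode raises it to 0.99.
The gain of 0.089 clears the 0.04 screen, beats both single-motif models,
none of 100 shuffled versions of the partner motif matched it (p < 0.01),
and it is an extreme outlier (Z = 99.7) among the nine candidates tested —
so the partner is declared a significant cooperative influence, which is the
planted ground truth.

The same analysis grid (all modes, both distance thresholds, accessibility
re-analysis, spacing-bias tests) runs end-to-end from a config via
`thermoccupancy run --config run.yaml`, or module by module through the
`thermoccupancy` CLI (`simulate`, `build-dataset`, `assess`, `spacing-bias`).

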