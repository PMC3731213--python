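"""Model-comparison statistics for secondary-motif influence detection.

A candidate secondary motif M2 is judged against the primary-only baseline by
the gain in cross-validated Pearson correlation, dCC = CC(M1+M2) - CC(M1),
and against the secondary-only model by dCC' = CC(M1+M2) - |CC(M2)|.  A
candidate is a significant influence when all four conditions hold:

1. dCC >= 0.04 (screen, applied before any shuffling),
2. dCC' >= 0.04,
3. empirical p-value <= 0.05, where the null dCC distribution comes from
   re-fitting with information-content-preserving shuffles of M2, and
4. modified Z-score >= 3, comparing this dCC to the dCC of every candidate
   secondary motif tested on the dataset (a robust outlier criterion that
   stands in for multiple-testing control).

Accessibility enters through the semi-partial correlation: the correlation
between predictions and ChIP scores after regressing accessibility out of
the ChIP scores, which separates accessibility-mediated influences from
accessibility-independent ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datasets import ChIPDataset
from .motifs import PWM, shuffle_pwm
from .training import CVFolds, FitResult, ModelConfig, cross_validate

__all__ = [
    "pearson_cc",
    "cc_pvalue",
    "modified_zscore",
    "roc_auc",
    "accessibility_filtered_scores",
    "semi_partial_cc",
    "subset_ccs",
    "gamma_expression_consistency",
    "InfluenceResult",
    "assess_secondary_influence",
    "assess_candidates",
    "DELTA_CC_MIN",
    "PVALUE_MAX",
    "ZSCORE_MIN",
]

DELTA_CC_MIN = 0.04
PVALUE_MAX = 0.05
ZSCORE_MIN = 3.0


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def cc_pvalue(r: float, n: int, tail: str = "two") -> float:
    """P-value of a Pearson correlation via the t-transform.

    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    if tail == "one":
        return float(stats.t.sf(t, df=n - 2))
    if tail == "two":
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    raise ValueError("tail must be 'one' or 'two'")


def modified_zscore(x: float, pool: Sequence[float]) -> float:
    """Robust outlier score: 0.6745 * (x - median) / MAD.

    With a zero median absolute deviation the denominator falls back to
    1.253314 times the mean absolute deviation about the median; if both
    vanish the score is undefined.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size < 3:
        raise ValueError("pool must hold at least 3 values")
    med = np.median(pool)
    mad = np.median(np.abs(pool - med))
    if mad > 0:
        return float(0.6745 * (x - med) / mad)
    mean_ad = np.mean(np.abs(pool - med))
    if mean_ad > 0:
        return float((x - med) / (1.253314 * mean_ad))
    raise ValueError("pool has zero spread; z-score undefined")


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based AUC (Mann-Whitney statistic); ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "bif":
        is_pos = labels.astype(bool)
    else:
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValueError("labels must contain exactly two classes")
        # "peak" > "nonpeak" alphabetically reversed; define positives as "peak"
        positive = "peak" if "peak" in uniq else uniq[1]
        is_pos = labels == positive
    n_pos = int(is_pos.sum())
    n_neg = int(is_pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def accessibility_filtered_scores(
    stap_scores: Sequence[float], accessible_flags: Sequence[bool]
) -> np.ndarray:
    """Predictions zeroed outside accessible windows."""
    scores = np.asarray(stap_scores, dtype=float)
    flags = np.asarray(accessible_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and flags must align")
    return scores * flags


def semi_partial_cc(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> float:
    """Semi-partial correlation of x with y after partialing z out of y.

    SPCC = (r_xy - r_xz * r_yz) / sqrt(1 - r_yz^2); identical to correlating
    x with the residuals of y regressed on z.
    """
    r_xy = pearson_cc(x, y)
    r_xz = pearson_cc(x, z)
    r_yz = pearson_cc(y, z)
    if abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("y and z are collinear; semi-partial correlation undefined")
    return float((r_xy - r_xz * r_yz) / np.sqrt(1.0 - r_yz * r_yz))


def subset_ccs(
    predictions: Sequence[float], chip: Sequence[float], labels: Sequence[str]
) -> dict[str, float]:
    """Overall, within-peak, and within-non-peak correlations."""
    predictions = np.asarray(predictions, dtype=float)
    chip = np.asarray(chip, dtype=float)
    labels = np.asarray(labels)
    out = {"overall": pearson_cc(predictions, chip)}
    for label in ("peak", "nonpeak"):
        mask = labels == label
        out[label] = pearson_cc(predictions[mask], chip[mask])
    return out


def gamma_expression_consistency(
    fit_a: FitResult,
    fit_b: FitResult,
    expr_a: float,
    expr_b: float,
) -> tuple[float, float, bool]:
    """Log ratio of fitted gammas vs log ratio of expression across stages.

    Returns (log10 gamma ratio, log10 expression ratio, same-sign flag);
    sign agreement places the point in the first or third quadrant,
    consistent with gamma tracking TF concentration.
    """
    if expr_a <= 0 or expr_b <= 0:
        raise ValueError("expression levels must be positive")
    ga = float(np.mean([p.log10_gamma[0] for p in fit_a.fold_params]))
    gb = float(np.mean([p.log10_gamma[0] for p in fit_b.fold_params]))
    log_gamma_ratio = ga - gb
    log_expr_ratio = float(np.log10(expr_a / expr_b))
    return log_gamma_ratio, log_expr_ratio, bool(log_gamma_ratio * log_expr_ratio >= 0)


@dataclass
class InfluenceResult:
    """Significance assessment of one candidate secondary motif."""

    dataset: str
    secondary: str
    mode: str
    d_T: int
    cc_m1: float
    cc_m2: float
    cc_m1m2: float
    delta_cc: float
    delta_cc_prime: float
    pvalue: float | None
    zscore: float
    significant: bool
    spcc_m1: float | None = None
    spcc_m1m2: float | None = None
    delta_spcc: float | None = None


def _cv_cc(
    dataset: ChIPDataset,
    pwms: Sequence[PWM],
    config: ModelConfig,
    folds: CVFolds,
) -> tuple[float, np.ndarray]:
    fit = cross_validate(dataset, config, folds, pwms=pwms)
    preds = fit.cv_predictions
    if np.std(preds) == 0:
        return 0.0, preds
    return pearson_cc(preds, dataset.chip), preds


def assess_candidates(
    dataset: ChIPDataset,
    primary: PWM,
    candidates: Sequence[PWM],
    mode: str,
    d_T: int,
    n_shuffles: int = 100,
    rng_seed: int = 0,
    folds: CVFolds | None = None,
    config: ModelConfig | None = None,
    use_accessibility: bool | None = None,
) -> list[InfluenceResult]:
    """Assess every candidate secondary motif on a dataset, sharing work.

    The baseline fit and the pool of dCC values (used by the Z-score) are
    computed once for all candidates.  Shuffled-motif p-values are computed
    only for candidates passing the dCC >= 0.04 screen; screened-out
    candidates report no p-value and are never significant.
    """
    if mode == "single":
        raise ValueError("influence assessment needs a two-motif mode")
    folds = folds or CVFolds.stratified(dataset.labels, seed=rng_seed)
    pair_config = config or ModelConfig(mode=mode, d_T=d_T)
    single_config = ModelConfig(
        mode="single",
        scan_min_rel_affinity=pair_config.scan_min_rel_affinity,
        refine=pair_config.refine,
        refine_maxfev=pair_config.refine_maxfev,
    )
    y = dataset.chip
    cc_m1, pred_m1 = _cv_cc(dataset, [primary], single_config, folds)

    if use_accessibility is None:
        use_accessibility = bool(np.isfinite(dataset.accessibility).all()) and bool(
            np.std(dataset.accessibility) > 0
        )

    entries = []
    for cand in candidates:
        cc_m2, _ = _cv_cc(dataset, [cand], single_config, folds)
        cc_m12, pred_m12 = _cv_cc(dataset, [primary, cand], pair_config, folds)
        entries.append((cand, cc_m2, cc_m12, pred_m12))

    pool = np.array([cc_m12 - cc_m1 for _, _, cc_m12, _ in entries])
    rng = np.random.default_rng(rng_seed)
    results: list[InfluenceResult] = []
    for (cand, cc_m2, cc_m12, pred_m12), delta in zip(entries, pool):
        delta_prime = cc_m12 - abs(cc_m2)
        try:
            z = modified_zscore(delta, pool)
        except ValueError:
            z = 0.0
        pvalue: float | None = None
        if delta >= DELTA_CC_MIN:
            null = np.empty(n_shuffles)
            for s in range(n_shuffles):
                shuf = shuffle_pwm(cand, rng)
                cc_shuf, _ = _cv_cc(dataset, [primary, shuf], pair_config, folds)
                null[s] = cc_shuf - cc_m1
            pvalue = float(np.mean(null >= delta))
        significant = (
            delta >= DELTA_CC_MIN
            and delta_prime >= DELTA_CC_MIN
            and pvalue is not None
            and pvalue <= PVALUE_MAX
            and z >= ZSCORE_MIN
        )
        spcc_m1 = spcc_m12 = delta_spcc = None
        if use_accessibility:
            acc = dataset.accessibility
            spcc_m1 = semi_partial_cc(pred_m1, y, acc)
            spcc_m12 = semi_partial_cc(pred_m12, y, acc)
            delta_spcc = spcc_m12 - spcc_m1
        results.append(
            InfluenceResult(
                dataset=dataset.name,
                secondary=cand.name,
                mode=mode,
                d_T=d_T,
                cc_m1=cc_m1,
                cc_m2=cc_m2,
                cc_m1m2=cc_m12,
                delta_cc=float(delta),
                delta_cc_prime=float(delta_prime),
                pvalue=pvalue,
                zscore=float(z),
                significant=bool(significant),
                spcc_m1=spcc_m1,
                spcc_m1m2=spcc_m12,
                delta_spcc=delta_spcc,
            )
        )
    return results


def assess_secondary_influence(
    dataset: ChIPDataset,
    primary: PWM,
    secondary: PWM,
    mode: str,
    d_T: int,
    n_shuffles: int = 100,
    candidate_pool: Sequence[PWM] = (),
    rng_seed: int = 0,
    folds: CVFolds | None = None,
    config: ModelConfig | None = None,
) -> InfluenceResult:
    """Full significance assessment of one secondary motif.

    ``candidate_pool`` supplies the other candidates whose dCC values form
    the Z-score reference pool (the motif under test is always included).
    """
    candidates = [secondary] + [p for p in candidate_pool if p is not secondary]
    results = assess_candidates(
        dataset,
        primary,
        candidates,
        mode,
        d_T,
        n_shuffles=n_shuffles,
        rng_seed=rng_seed,
        folds=folds,
        config=config,
    )
    return results[0]
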