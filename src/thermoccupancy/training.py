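"""Fitting the free parameters of a binding model to ChIP scores.

The model has one free parameter per motif (gamma, searched on a log10 grid
within [1, 1e4]) plus, in the interaction modes, the interaction term omega
(cooperative: [1, 100]; antagonistic: [0.01, 1]).  The training objective is
the Pearson correlation between predicted occupancies and ChIP scores —
scale-free, matching how fits are evaluated.  A coarse grid search is
followed by derivative-free local refinement (Nelder–Mead) from the best
grid point.

Evaluation uses stratified 4-fold cross-validation: peaks and non-peaks are
partitioned separately so each test fold holds equal shares of both, the
model is fitted on the other three folds and predicts the held-out quarter,
and the concatenated out-of-fold predictions are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import ChIPDataset
from .motifs import PWM
from .stap_core import MODES, SiteTable

__all__ = ["ModelConfig", "CVFolds", "FitParams", "FitResult", "fit_params", "cross_validate"]


def safe_cc(pred: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, defined as 0 when predictions are constant."""
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


def _row_correlations(preds: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``preds`` with ``y`` (0 if constant)."""
    pc = preds - preds.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((pc * pc).sum(axis=1)) * np.sqrt((yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (pc @ yc) / denom
    return np.where(denom > 0, cc, 0.0)


@dataclass
class ModelConfig:
    """Search space and scanning threshold for one binding-model fit."""

    mode: str = "single"
    d_T: int = 150
    gamma_bounds: tuple[float, float] = (1.0, 1e4)
    log10_gamma_step: float = 0.5
    omega_bounds: tuple[float, float] | None = None  # defaults by mode
    log10_omega_step: float = 0.5
    scan_min_rel_affinity: float = 0.01
    refine: bool = True
    refine_maxfev: int = 80
    refine_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.omega_bounds is None:
            self.omega_bounds = {
                "single": (1.0, 1.0),
                "competition": (1.0, 1.0),
                "cooperative": (1.0, 100.0),
                "antagonistic": (0.01, 1.0),
            }[self.mode]

    @property
    def n_motifs(self) -> int:
        return 1 if self.mode == "single" else 2

    def gamma_grid(self) -> np.ndarray:
        lo, hi = np.log10(self.gamma_bounds)
        return np.arange(lo, hi + 1e-9, self.log10_gamma_step)

    def omega_grid(self) -> np.ndarray:
        lo, hi = np.log10(self.omega_bounds)
        if hi - lo < 1e-12:
            return np.array([lo])
        return np.arange(lo, hi + 1e-9, self.log10_omega_step)

    def grid_points(self) -> np.ndarray:
        """All (log10 gamma..., log10 omega) coarse-grid combinations."""
        gg = self.gamma_grid()
        og = self.omega_grid()
        if self.n_motifs == 1:
            mesh = np.meshgrid(gg, og, indexing="ij")
        else:
            mesh = np.meshgrid(gg, gg, og, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


@dataclass
class FitParams:
    """Fitted parameters on the log10 scale, plus the training objective."""

    log10_gamma: tuple[float, ...]
    omega: float
    objective: float

    @property
    def gamma(self) -> tuple[float, ...]:
        return tuple(10.0 ** g for g in self.log10_gamma)


@dataclass
class CVFolds:
    """Window -> fold assignment, stratified by peak/non-peak label."""

    k: int
    assignments: np.ndarray
    seed: int

    @classmethod
    def stratified(cls, labels: Sequence[str], k: int = 4, seed: int = 0) -> "CVFolds":
        labels = np.asarray(labels)
        rng = np.random.default_rng(seed)
        assignments = np.empty(labels.size, dtype=np.int64)
        for label in np.unique(labels):
            idx = np.nonzero(labels == label)[0]
            perm = rng.permutation(idx)
            for f in range(k):
                assignments[perm[f::k]] = f
        return cls(k=k, assignments=assignments, seed=seed)


@dataclass
class FitResult:
    """Per-fold parameters and concatenated out-of-fold predictions."""

    fold_params: list[FitParams]
    cv_predictions: np.ndarray
    fold_objectives: list[float]
    consistency_flag: bool
    folds: CVFolds


def _params_vector_to_fit(x: np.ndarray, config: ModelConfig, objective: float) -> FitParams:
    if config.n_motifs == 1:
        return FitParams((float(x[0]),), 10.0 ** float(x[-1]), objective)
    return FitParams((float(x[0]), float(x[1])), 10.0 ** float(x[-1]), objective)


def _fit_on_table(
    table: SiteTable,
    y: np.ndarray,
    config: ModelConfig,
    grid: np.ndarray | None = None,
    grid_preds: np.ndarray | None = None,
) -> FitParams:
    """Grid search (optionally with precomputed predictions) plus refinement."""
    if np.unique(y).size < 2:
        raise ValueError("training scores are constant; correlation undefined")
    if grid is None:
        grid = config.grid_points()
    if grid_preds is None:
        grid_preds = np.stack(
            [
                table.predict(10.0 ** x[:-1], 10.0 ** x[-1], config.d_T)
                for x in grid
            ]
        )
    ccs = _row_correlations(grid_preds, y)
    best_idx = int(np.argmax(ccs))
    x0 = grid[best_idx].copy()
    best_cc = float(ccs[best_idx])
    if not config.refine:
        return _params_vector_to_fit(x0, config, best_cc)

    lo_g, hi_g = np.log10(config.gamma_bounds)
    lo_o, hi_o = np.log10(config.omega_bounds)
    lows = np.array([lo_g] * config.n_motifs + [lo_o])
    highs = np.array([hi_g] * config.n_motifs + [hi_o])
    free = highs - lows > 1e-12

    def objective(x: np.ndarray) -> float:
        return safe_cc(
            table.predict(10.0 ** x[: config.n_motifs], 10.0 ** x[-1], config.d_T), y
        )

    # coordinate pattern search from the best grid point: propose +/- step
    # moves per free coordinate, accept the best improvement, halve the step
    # when stuck; stops at the objective tolerance or the evaluation budget.
    x, fx = x0, best_cc
    steps = np.array(
        [config.log10_gamma_step / 2] * config.n_motifs + [config.log10_omega_step / 2]
    )
    evals = 0
    while evals < config.refine_maxfev and steps.max() > 0.02:
        improved = False
        for d in np.nonzero(free)[0]:
            for sign in (1.0, -1.0):
                cand = x.copy()
                cand[d] = np.clip(cand[d] + sign * steps[d], lows[d], highs[d])
                if cand[d] == x[d]:
                    continue
                fc = objective(cand)
                evals += 1
                if fc > fx + 1e-12:
                    gain = fc - fx
                    x, fx = cand, fc
                    improved = True
                    if gain < config.refine_tol:
                        improved = False
                    break
        if not improved:
            steps = steps / 2.0
    return _params_vector_to_fit(x, config, fx)


def fit_params(
    train_windows,
    model_config: ModelConfig,
    scan_threshold: float | None = None,
    pwms: Sequence[PWM] | None = None,
) -> FitParams:
    """Fit gamma (and omega) maximizing training Pearson correlation.

    ``train_windows`` is a ChIPDataset (or any object with ``seq_matrix`` and
    ``chip``); ``pwms`` defaults to the dataset's primary motif.
    """
    pwms = _resolve_pwms(train_windows, model_config, pwms)
    thr = scan_threshold or model_config.scan_min_rel_affinity
    table = SiteTable.build(train_windows.seq_matrix, pwms, thr)
    return _fit_on_table(table, train_windows.chip, model_config)


def _resolve_pwms(dataset, config: ModelConfig, pwms: Sequence[PWM] | None) -> list[PWM]:
    if pwms is None:
        if getattr(dataset, "primary_motif", None) is None:
            raise ValueError("no motifs supplied and dataset has no primary motif")
        pwms = [dataset.primary_motif]
    pwms = list(pwms)
    if len(pwms) != config.n_motifs:
        raise ValueError(
            f"{config.mode} mode needs {config.n_motifs} motif(s), got {len(pwms)}"
        )
    return pwms


def cross_validate(
    dataset: ChIPDataset,
    model_config: ModelConfig,
    folds: CVFolds | None = None,
    pwms: Sequence[PWM] | None = None,
    site_table: SiteTable | None = None,
) -> FitResult:
    """Out-of-fold occupancy predictions under k-fold cross-validation.

    Coarse-grid predictions are computed once for all windows and shared
    across folds (parameters, not predictions, are what differ per fold);
    refinement then polishes each fold's optimum on its training windows
    only.  The consistency flag is False when the per-fold primary log10
    gamma values span more than 2 decades — the surrogate for discarding a
    dataset whose folds disagree.
    """
    pwms = _resolve_pwms(dataset, model_config, pwms)
    if site_table is None:
        site_table = SiteTable.build(
            dataset.seq_matrix, pwms, model_config.scan_min_rel_affinity
        )
    y = dataset.chip
    folds = folds or CVFolds.stratified(dataset.labels, seed=0)
    grid = model_config.grid_points()
    grid_preds = np.stack(
        [
            site_table.predict(10.0 ** x[:-1], 10.0 ** x[-1], model_config.d_T)
            for x in grid
        ]
    )
    cv_pred = np.full(len(dataset), np.nan)
    fold_params: list[FitParams] = []
    fold_objectives: list[float] = []
    for f in range(folds.k):
        test_mask = folds.assignments == f
        train_idx = np.nonzero(~test_mask)[0]
        test_idx = np.nonzero(test_mask)[0]
        try:
            fit = _fit_on_table(
                site_table.subset(train_idx),
                y[train_idx],
                model_config,
                grid=grid,
                grid_preds=grid_preds[:, train_idx],
            )
        except ValueError as exc:
            raise RuntimeError(f"fit failed in fold {f}: {exc}") from exc
        fold_params.append(fit)
        fold_objectives.append(fit.objective)
        test_table = site_table.subset(test_idx)
        cv_pred[test_idx] = test_table.predict(fit.gamma, fit.omega, model_config.d_T)
    primary_gammas = [p.log10_gamma[0] for p in fold_params]
    consistent = (max(primary_gammas) - min(primary_gammas)) <= 2.0
    return FitResult(
        fold_params=fold_params,
        cv_predictions=cv_pred,
        fold_objectives=fold_objectives,
        consistency_flag=consistent,
        folds=folds,
    )
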