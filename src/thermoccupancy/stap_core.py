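"""Statistical-thermodynamics model of TF occupancy in a sequence window.

A molecular configuration sigma selects a subset of non-overlapping candidate
binding sites to be simultaneously bound.  Its Boltzmann weight is

    W(sigma) = prod_{S bound} q(S) * prod_{interacting pairs} omega,

where q(S) = gamma_TF * exp(LLR(S) - LLR(S_max)) couples the TF-specific free
parameter gamma (equilibrium constant of the consensus site times TF
concentration) to the site's relative affinity, and omega multiplies the
weight of configurations in which a bound primary site and a bound secondary
site are adjacent (no bound site between them) and separated by at most the
distance threshold d_T.  omega > 1 models cooperative and omega < 1
antagonistic influence; omega = 1 (the "competition" mode with two motifs)
leaves overlapping-site exclusion as the only coupling.

The predicted occupancy of the primary TF is the expectation of its bound-site
count under the Boltzmann distribution:

    OCC = sum_sigma N_primary(sigma) W(sigma) / sum_sigma W(sigma).

Both a brute-force enumerator (the oracle, exponential in site count) and an
exact dynamic program (linear-scan over sites, used everywhere else) are
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import motifs as _motifs
from ._kernels import occ_batch
from .motifs import PWM, Site

__all__ = [
    "MODES",
    "BindingModel",
    "Configuration",
    "site_weight",
    "enumerate_configurations",
    "occupancy_brute_force",
    "occupancy_dp",
    "predict_window",
    "SiteTable",
]

MODES = ("single", "cooperative", "antagonistic", "competition")

_MAX_ENUMERATE = 25

GAMMA_BOUNDS_DEFAULT = (1.0, 1e4)


@dataclass
class BindingModel:
    """Motif set with thermodynamic parameters and interaction mode.

    ``motifs`` holds one PWM (single mode) or two (primary first).  ``gamma``
    is the per-motif TF-specific parameter; ``omega`` the interaction term;
    ``d_T`` the maximum separation (gap in bp between site intervals) at which
    the interaction applies.
    """

    motifs: Sequence[PWM]
    gamma: Sequence[float]
    omega: float = 1.0
    d_T: int = 150
    mode: str = "single"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        n = len(self.motifs)
        if self.mode == "single":
            if n != 1:
                raise ValueError("single mode uses exactly one motif")
        elif n != 2:
            raise ValueError(f"{self.mode} mode uses exactly two motifs")
        self.gamma = [float(g) for g in self.gamma]
        if len(self.gamma) != n or any(g <= 0 for g in self.gamma):
            raise ValueError("gamma must hold one positive value per motif")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.mode in ("single", "competition") and self.omega != 1.0:
            raise ValueError(f"{self.mode} mode requires omega == 1")
        if self.mode == "cooperative" and self.omega < 1.0:
            raise ValueError("cooperative mode requires omega >= 1")
        if self.mode == "antagonistic" and self.omega > 1.0:
            raise ValueError("antagonistic mode requires omega <= 1")

    def motif_index(self, name: str) -> int:
        for i, pwm in enumerate(self.motifs):
            if pwm.name == name:
                return i
        raise KeyError(f"site motif {name!r} not in model motifs")


@dataclass(frozen=True)
class Configuration:
    """A set of simultaneously bound, non-overlapping sites with its weight."""

    bound: tuple[Site, ...]
    weight: float
    n_primary: int


def site_weight(site: Site, gamma: float) -> float:
    """Statistical weight q(S) = gamma * exp(LLR(S) - LLR(S_max))."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return gamma * site.rel_affinity


def _config_weight(bound: Sequence[Site], model: BindingModel) -> tuple[float, int]:
    """Boltzmann weight and primary-site count of a sorted non-overlapping set."""
    w = 1.0
    n_primary = 0
    prev: Site | None = None
    for site in bound:
        idx = model.motif_index(site.motif)
        w *= site_weight(site, model.gamma[idx])
        if idx == 0:
            n_primary += 1
        if prev is not None:
            gap = site.start - prev.end
            if (
                model.motif_index(prev.motif) != idx
                and 0 <= gap <= model.d_T
            ):
                w *= model.omega
        prev = site
    return w, n_primary


def enumerate_configurations(
    sites: Sequence[Site], model: BindingModel
) -> list[Configuration]:
    """All non-overlapping subsets of ``sites`` with their Boltzmann weights.

    Includes the empty configuration (weight 1).  Intended as a small-scale
    oracle; raises for more than 25 sites (use :func:`occupancy_dp`).
    """
    if len(sites) > _MAX_ENUMERATE:
        raise ValueError(
            f"{len(sites)} sites is too many to enumerate; use occupancy_dp"
        )
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.strand))
    configs: list[Configuration] = []

    def recurse(idx: int, chosen: list[Site]) -> None:
        if idx == len(ordered):
            w, n_primary = _config_weight(chosen, model)
            configs.append(Configuration(tuple(chosen), w, n_primary))
            return
        recurse(idx + 1, chosen)
        cand = ordered[idx]
        if all(cand.start >= s.end or cand.end <= s.start for s in chosen):
            chosen.append(cand)
            recurse(idx + 1, chosen)
            chosen.pop()

    recurse(0, [])
    return configs


def occupancy_brute_force(sites: Sequence[Site], model: BindingModel) -> float:
    """Expected bound primary-site count by explicit configuration sums."""
    configs = enumerate_configurations(sites, model)
    total_w = sum(c.weight for c in configs)
    total_n = sum(c.n_primary * c.weight for c in configs)
    return total_n / total_w


def occupancy_dp(sites: Sequence[Site], model: BindingModel) -> float:
    """Expected bound primary-site count by the last-bound-site DP.

    Equals :func:`occupancy_brute_force` to high relative precision for any
    site count, at polynomial cost.
    """
    n = len(sites)
    if n == 0:
        return 0.0
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.strand))
    starts = np.array([s.start for s in ordered], dtype=np.int64)
    ends = np.array([s.end for s in ordered], dtype=np.int64)
    mids = np.array(
        [model.motif_index(s.motif) for s in ordered], dtype=np.int8
    )
    relaff = np.array([s.rel_affinity for s in ordered])
    g0 = model.gamma[0]
    g1 = model.gamma[1] if len(model.gamma) > 1 else 1.0
    out = np.zeros(1)
    ptr = np.array([0, n], dtype=np.int64)
    occ_batch(ptr, starts, ends, mids, relaff, g0, g1, model.omega, float(model.d_T), out)
    return float(out[0])


def predict_window(
    window_seq: str, model: BindingModel, scan_threshold: float = 0.01
) -> float:
    """Occupancy prediction for one sequence window.

    Scans every model motif at the relative-affinity threshold, merges the
    candidate sites, and runs the occupancy DP for the primary motif.
    """
    sites: list[Site] = []
    for pwm in model.motifs:
        sites.extend(
            _motifs.scan_sites(pwm, window_seq, min_rel_affinity=scan_threshold)
        )
    return occupancy_dp(sites, model)


@dataclass
class SiteTable:
    """Candidate sites for a batch of equal-length windows, CSR layout.

    Built once per (window set, motif set, threshold); occupancy predictions
    for any parameter values are then a single kernel call.
    """

    ptr: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    motif_ids: np.ndarray
    relaff: np.ndarray
    n_windows: int

    @classmethod
    def build(
        cls,
        seq_matrix: np.ndarray,
        pwms: Sequence[PWM],
        min_rel_affinity: float = 0.01,
    ) -> "SiteTable":
        n_windows = seq_matrix.shape[0]
        win_parts: list[np.ndarray] = []
        start_parts: list[np.ndarray] = []
        end_parts: list[np.ndarray] = []
        mid_parts: list[np.ndarray] = []
        aff_parts: list[np.ndarray] = []
        for mid, pwm in enumerate(pwms):
            thr = pwm.llr_max + np.log(min_rel_affinity)
            w_idx, start, _, llr = _motifs.scan_encoded(pwm, seq_matrix, thr)
            win_parts.append(w_idx)
            start_parts.append(start)
            end_parts.append(start + pwm.length)
            mid_parts.append(np.full(w_idx.size, mid, dtype=np.int8))
            aff_parts.append(np.exp(np.minimum(llr - pwm.llr_max, 0.0)))
        win = np.concatenate(win_parts)
        starts = np.concatenate(start_parts).astype(np.int64)
        ends = np.concatenate(end_parts).astype(np.int64)
        mids = np.concatenate(mid_parts)
        affs = np.concatenate(aff_parts)
        order = np.lexsort((ends, starts, win))
        win = win[order]
        counts = np.bincount(win, minlength=n_windows)
        ptr = np.zeros(n_windows + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        return cls(
            ptr=ptr,
            starts=starts[order],
            ends=ends[order],
            motif_ids=mids[order],
            relaff=affs[order],
            n_windows=n_windows,
        )

    def subset(self, indices: np.ndarray) -> "SiteTable":
        """Table restricted to the given window indices (renumbered 0..k-1)."""
        indices = np.asarray(indices)
        parts = [np.arange(self.ptr[i], self.ptr[i + 1]) for i in indices]
        take = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        counts = np.array([self.ptr[i + 1] - self.ptr[i] for i in indices])
        ptr = np.zeros(indices.size + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        return SiteTable(
            ptr=ptr,
            starts=self.starts[take],
            ends=self.ends[take],
            motif_ids=self.motif_ids[take],
            relaff=self.relaff[take],
            n_windows=indices.size,
        )

    def predict(self, gamma: Sequence[float], omega: float, d_T: float) -> np.ndarray:
        """Occupancy of the primary motif for every window at these parameters."""
        out = np.zeros(self.n_windows)
        g0 = float(gamma[0])
        g1 = float(gamma[1]) if len(gamma) > 1 else 1.0
        occ_batch(
            self.ptr,
            self.starts,
            self.ends,
            self.motif_ids,
            self.relaff,
            g0,
            g1,
            float(omega),
            float(d_T),
            out,
        )
        return out
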