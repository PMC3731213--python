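"""Synthetic regulatory-sequence datasets with known ground truth.

The generator emulates the statistical structure the occupancy analysis
assumes: 500 bp windows of i.i.d. background sequence at fly-like GC content
(0.41), primary and secondary binding sites planted with controlled rates,
spacings and overlaps, ChIP-like scores produced by the true thermodynamic
model plus additive Gaussian noise, an accessibility signal that can either
merely correlate with binding or actively gate it (the pioneer-factor
scenario), and a stage-by-gene expression table for candidate ranking.

Planted sites are sampled base-by-base from the motif's probability columns,
so site strengths vary realistically around the consensus.  Every planted
site is recorded in a manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ChIPDataset, GenomicWindow
from .motifs import PWM, decode_seq, information_content
from .stap_core import BindingModel, SiteTable

__all__ = [
    "TruthModel",
    "gen_pwm",
    "gen_windows",
    "gen_chip_scores",
    "gen_expression_table",
    "simulate_dataset",
    "SimulatedSignal",
]

WINDOW_LENGTH = 500
DEFAULT_GC = 0.41
# Noise scale on the occupancy axis.  The generator's role is ground-truth
# validation, so the regime is favorable: the true model attains correlations
# around 0.9-0.97, and each planted interaction contributes a clearly
# detectable share of the signal variance at the few-hundred-window scale.
# Real embryonic ChIP data is far noisier.
DEFAULT_NOISE_SD = 0.1


@dataclass
class TruthModel:
    """Generating model: motifs, thermodynamic parameters, planting scheme.

    ``mode`` names the interaction wired into the generating model.  In the
    ``accessibility`` = "mediated" scenario the secondary motif does NOT
    enter the binding model; its sites act as a latent pioneer signal that
    raises accessibility, which in turn gates the ChIP signal.
    """

    primary: PWM
    secondary: PWM | None = None
    log10_gamma: tuple[float, float] = (1.0, 1.0)
    omega: float = 1.0
    d_T: int = 150
    mode: str = "single"
    primary_rate: float = 0.5
    sites_per_window: tuple[int, int] = (1, 1)
    secondary_given_primary: float = 0.7
    secondary_alone_rate: float = 0.15
    spacing: int | None = None  # fixed gap; None = uniform over [5, spacing_max]
    overlap_bases: int = 4  # competition-mode site overlap
    noise_sd: float = DEFAULT_NOISE_SD
    accessibility: str = "none"  # none | correlated | mediated
    inaccessible_fraction: float = 0.5
    access_noise: float = 0.3

    def binding_model(self) -> BindingModel:
        gammas = [10.0 ** self.log10_gamma[0]]
        motifs = [self.primary]
        if self.mode != "single":
            if self.secondary is None:
                raise ValueError(f"{self.mode} truth needs a secondary motif")
            motifs.append(self.secondary)
            gammas.append(10.0 ** self.log10_gamma[1])
        omega = self.omega if self.mode in ("cooperative", "antagonistic") else 1.0
        return BindingModel(
            motifs=motifs, gamma=gammas, omega=omega, d_T=self.d_T, mode=self.mode
        )

    @property
    def spacing_max(self) -> int:
        return max(self.d_T, 6)

    # -- factories for the standard study conditions ----------------------

    @classmethod
    def cooperative(cls, seed: int = 0, d_T: int = 150, **kw) -> "TruthModel":
        """Cooperative pair: moderately concentrated primary, a somewhat more
        abundant partner, strong synergy (omega = 10)."""
        rng = np.random.SeedSequence(seed).spawn(2)
        kw.setdefault("log10_gamma", (1.0, 1.5))
        return cls(
            primary=gen_pwm(8, 10.0, rng[0]),
            secondary=gen_pwm(8, 10.0, rng[1]),
            omega=10.0,
            mode="cooperative",
            d_T=d_T,
            **kw,
        )

    @classmethod
    def antagonistic(cls, seed: int = 0, d_T: int = 150, **kw) -> "TruthModel":
        """Antagonistic pair: an abundant repressive partner with a strongly
        unfavorable interaction energy (omega = 0.02)."""
        rng = np.random.SeedSequence(seed).spawn(2)
        kw.setdefault("log10_gamma", (1.5, 2.0))
        return cls(
            primary=gen_pwm(8, 10.0, rng[0]),
            secondary=gen_pwm(8, 10.0, rng[1]),
            omega=0.02,
            mode="antagonistic",
            d_T=d_T,
            **kw,
        )

    @classmethod
    def competition(cls, seed: int = 0, overlap_bases: int = 4, **kw) -> "TruthModel":
        """Competition truth with motifs whose consensi share a substring.

        The secondary motif's leading columns are sharpened to match the tail
        of the primary consensus, so intact sites of both motifs can coexist
        at overlapping positions in the planted sequence.
        """
        rng = np.random.SeedSequence(seed).spawn(2)
        kw.setdefault("log10_gamma", (1.0, 2.5))
        primary = gen_pwm(8, 10.0, rng[0])
        secondary = gen_pwm(8, 10.0, rng[1])
        probs = secondary.probs.copy()
        tail = primary.consensus[-overlap_bases:]
        for i, base in enumerate(tail):
            col = np.full(4, 0.05 / 3)
            col["ACGT".index(base)] = 0.95
            probs[i] = col
        secondary = secondary.without_pseudocount(name=secondary.name, probs=probs)
        return cls(
            primary=primary,
            secondary=secondary,
            omega=1.0,
            mode="competition",
            overlap_bases=overlap_bases,
            **kw,
        )

    @classmethod
    def accessibility_mediated(cls, seed: int = 0, **kw) -> "TruthModel":
        rng = np.random.SeedSequence(seed).spawn(2)
        return cls(
            primary=gen_pwm(8, 10.0, rng[0]),
            secondary=gen_pwm(8, 10.0, rng[1]),
            mode="single",
            accessibility="mediated",
            **kw,
        )


def gen_pwm(
    length: int,
    information_bits: float,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> PWM:
    """Random PWM with total information content within 5% of the target.

    Random Dirichlet column profiles are raised to a shared temperature
    exponent, chosen by bisection so the (pseudocount-adjusted) information
    content hits the target.  Deterministic for a fixed seed.
    """
    if not 4 <= length <= 20:
        raise ValueError("length must be in [4, 20]")
    if not 0 < information_bits:
        raise ValueError("information_bits must be positive")
    rng = np.random.default_rng(rng_seed)
    name = f"pwm_{rng.integers(0, 2**32):08x}"
    base = rng.dirichlet(np.ones(4), size=length)
    # break ties so each column has a unique consensus base
    base = base + rng.uniform(0, 1e-6, base.shape)

    def build(tau: float) -> PWM:
        probs = base ** tau
        probs /= probs.sum(axis=1, keepdims=True)
        return PWM(name=name, probs=probs)

    hi = 400.0
    max_ic = information_content(build(hi))
    if information_bits > max_ic:
        raise ValueError(
            f"target {information_bits} bits unattainable for length {length} "
            f"(max ~{max_ic:.2f} with pseudocount)"
        )
    lo = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if information_content(build(mid)) < information_bits:
            lo = mid
        else:
            hi = mid
    pwm = build(0.5 * (lo + hi))
    ic = information_content(pwm)
    if abs(ic - information_bits) > 0.05 * information_bits:
        raise RuntimeError(f"IC bisection failed: {ic:.3f} vs {information_bits}")
    return pwm


def _sample_site(pwm: PWM, rng: np.random.Generator) -> np.ndarray:
    """Draw one site, base-by-base, from the motif's probability columns."""
    u = rng.random(pwm.length)
    cum = np.cumsum(pwm.probs, axis=1)
    return (u[:, None] < cum).argmax(axis=1).astype(np.uint8)


def _place(
    seq: np.ndarray, start: int, codes: np.ndarray, strand: int
) -> None:
    if strand == 1:
        codes = 3 - codes[::-1]
    seq[start : start + codes.size] = codes


def gen_windows(
    n_windows: int,
    truth: TruthModel,
    rng_seed: int | np.random.Generator = 0,
    length: int = WINDOW_LENGTH,
    gc: float = DEFAULT_GC,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Background windows with planted sites; returns (seq matrix, manifest).

    The manifest records every planted site: window index, role
    (primary/secondary), start, strand, and — for secondary sites planted
    relative to a primary partner — the inter-site gap.
    """
    rng = np.random.default_rng(rng_seed)
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = rng.choice(4, size=(n_windows, length), p=p_bg).astype(np.uint8)
    L1 = truth.primary.length
    L2 = truth.secondary.length if truth.secondary is not None else 0
    records: list[dict] = []

    for w in range(n_windows):
        has_primary = rng.random() < truth.primary_rate
        if has_primary:
            lo, hi = truth.sites_per_window
            n_sites = int(rng.integers(lo, hi + 1))
            placed: list[tuple[int, int]] = []
            for _ in range(n_sites):
                for _attempt in range(50):
                    start = int(rng.integers(10, length - L1 - truth.spacing_max - L2 - 10))
                    if all(start + L1 + 2 <= s or start >= e + 2 for s, e in placed):
                        break
                else:
                    continue
                # overlapping-site planting aligns the shared consensus
                # substring, which pins the competition pair to plus strand
                strand = 0 if truth.mode == "competition" else int(rng.integers(0, 2))
                _place(seqs[w], start, _sample_site(truth.primary, rng), strand)
                placed.append((start, start + L1))
                records.append(
                    {"window": w, "role": "primary", "start": start,
                     "strand": "+-"[strand], "gap": np.nan}
                )
            if (
                truth.secondary is not None
                and placed
                and rng.random() < truth.secondary_given_primary
            ):
                p_start, p_end = placed[0]
                if truth.mode == "competition":
                    gap = -truth.overlap_bases
                    s_start = p_end + gap
                elif truth.spacing is not None:
                    gap = truth.spacing
                    s_start = p_end + gap
                else:
                    gap = int(rng.integers(5, truth.spacing_max - L2 + 1))
                    s_start = p_end + gap
                if 0 <= s_start <= length - L2:
                    strand = 0 if truth.mode == "competition" else int(rng.integers(0, 2))
                    _place(seqs[w], s_start, _sample_site(truth.secondary, rng), strand)
                    records.append(
                        {"window": w, "role": "secondary", "start": s_start,
                         "strand": "+-"[strand], "gap": gap}
                    )
        elif truth.secondary is not None and rng.random() < truth.secondary_alone_rate:
            s_start = int(rng.integers(10, length - L2 - 10))
            strand = int(rng.integers(0, 2))
            _place(seqs[w], s_start, _sample_site(truth.secondary, rng), strand)
            records.append(
                {"window": w, "role": "secondary", "start": s_start,
                 "strand": "+-"[strand], "gap": np.nan}
            )
    manifest = pd.DataFrame(records, columns=["window", "role", "start", "strand", "gap"])
    return seqs, manifest


@dataclass
class SimulatedSignal:
    """ChIP-like scores with the latent quantities that produced them."""

    scores: np.ndarray
    occupancy: np.ndarray
    accessibility: np.ndarray | None
    accessible: np.ndarray | None


def gen_chip_scores(
    seq_matrix: np.ndarray,
    truth: TruthModel,
    rng_seed: int | np.random.Generator = 0,
    scan_threshold: float = 0.01,
) -> SimulatedSignal:
    """Scores = occupancy under the true model (+ optional accessibility gate)
    + additive Gaussian noise."""
    rng = np.random.default_rng(rng_seed)
    model = truth.binding_model()
    table = SiteTable.build(seq_matrix, model.motifs, scan_threshold)
    occ = table.predict(model.gamma, model.omega, model.d_T)

    accessibility = None
    accessible = None
    signal = occ
    if truth.accessibility != "none":
        primary_table = SiteTable.build(seq_matrix, [truth.primary], scan_threshold)
        occ_primary = primary_table.predict([model.gamma[0]], 1.0, truth.d_T)
        if truth.accessibility == "correlated":
            spread = np.std(occ_primary) or 1.0
            accessibility = occ_primary + rng.normal(
                0, truth.access_noise * spread, occ.size
            )
            accessible = accessibility >= np.quantile(accessibility, 0.9)
        elif truth.accessibility == "mediated":
            if truth.secondary is None:
                raise ValueError("mediated accessibility needs a pioneer motif")
            pioneer = SiteTable.build(seq_matrix, [truth.secondary], scan_threshold)
            counts = np.diff(pioneer.ptr).astype(float)
            accessibility = counts + rng.normal(0, truth.access_noise, occ.size)
            gate = accessibility >= np.quantile(
                accessibility, truth.inaccessible_fraction
            )
            accessible = gate
            signal = occ * gate
        else:
            raise ValueError(f"unknown accessibility mode {truth.accessibility!r}")
    scores = signal + rng.normal(0, truth.noise_sd, occ.size)
    return SimulatedSignal(
        scores=scores, occupancy=signal, accessibility=accessibility, accessible=accessible
    )


def gen_expression_table(
    tfs: Sequence[str],
    stages: Sequence,
    rng_seed: int = 0,
    top_tfs: Sequence[str] = (),
    scale: float = 1.0,
) -> pd.DataFrame:
    """Positive expression levels per (gene, stage); designated TFs forced to
    the top of every stage's ranking."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for stage in stages:
        levels = np.exp(rng.normal(2.0, 1.0, len(tfs))) * scale
        top = float(levels.max())
        for i, tf in enumerate(tfs):
            level = levels[i]
            if tf in top_tfs:
                level = top * (2.0 + list(top_tfs).index(tf))
            rows.append({"gene": tf, "stage": stage, "level": float(level)})
    return pd.DataFrame(rows)


def simulate_dataset(
    truth: TruthModel,
    n_peaks: int = 1000,
    n_nonpeaks: int = 1000,
    seed: int = 0,
    name: str | None = None,
    pool_factor: int = 2,
) -> tuple[ChIPDataset, pd.DataFrame]:
    """Full synthetic ChIP dataset: generate, score, and select windows.

    A pool of ``pool_factor * (n_peaks + n_nonpeaks)`` windows is generated;
    the top-scoring ``n_peaks`` become peaks and ``n_nonpeaks`` are sampled
    uniformly (seeded) from the remainder, mirroring how real datasets pick
    peaks and random negatives.  Returns the dataset and the planted-site
    manifest (window indices refer to positions within the dataset; windows
    not selected are dropped from the manifest).
    """
    ss = np.random.SeedSequence(seed)
    seq_rng, score_rng, pick_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    n_pool = pool_factor * (n_peaks + n_nonpeaks)
    seqs, manifest = gen_windows(n_pool, truth, seq_rng)
    sig = gen_chip_scores(seqs, truth, score_rng)

    order = np.argsort(-sig.scores, kind="stable")
    peak_idx = order[:n_peaks]
    rest = order[n_peaks:]
    nonpeak_idx = pick_rng.choice(rest, size=n_nonpeaks, replace=False)

    if truth.accessibility != "none":
        acc = sig.accessibility
        if truth.accessibility == "mediated":
            threshold = np.quantile(acc, truth.inaccessible_fraction)
        else:
            threshold = np.quantile(acc, 0.9)

    windows: list[GenomicWindow] = []
    keep: dict[int, int] = {}
    for label, idx_arr in (("peak", peak_idx), ("nonpeak", nonpeak_idx)):
        for i in idx_arr:
            i = int(i)
            keep[i] = len(windows)
            w = GenomicWindow(
                chrom="synth",
                start=len(windows) * WINDOW_LENGTH,
                end=(len(windows) + 1) * WINDOW_LENGTH,
                seq=decode_seq(seqs[i]),
                chip_score=float(sig.scores[i]),
                label=label,
            )
            if truth.accessibility != "none":
                w.accessibility = float(sig.accessibility[i])
                w.accessible = bool(sig.accessibility[i] >= threshold)
            windows.append(w)

    manifest = manifest[manifest["window"].isin(keep)].copy()
    manifest["window"] = manifest["window"].map(keep)
    dataset = ChIPDataset(
        name=name or f"SYNTH_{truth.mode}_dt{truth.d_T}",
        windows=windows,
        primary_motif=truth.primary,
    )
    return dataset, manifest.reset_index(drop=True)
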