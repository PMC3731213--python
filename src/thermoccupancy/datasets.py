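"""Dataset construction: smoothed signal windows, peak/non-peak selection,
accessibility attachment, and motif/candidate selection.

A ChIP (or accessibility) track is smoothed onto a grid of 500 bp windows
spaced every 50 bp: each raw position/score pair is mapped to the nearest
multiple of 50 and a window's score is the mean of all raw scores mapped
into it (0 where no score maps).  A dataset is the top-N non-overlapping
highest-scoring windows ("peaks") plus N randomly drawn non-exonic,
non-overlapping windows ("non-peaks").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import PWM, encode_seq

__all__ = [
    "GenomicWindow",
    "ChIPDataset",
    "smooth_track",
    "smooth_genome",
    "build_dataset",
    "select_primary_motif",
    "rank_secondary_candidates",
    "attach_accessibility",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_track",
    "write_dataset",
]

WINDOW = 500
STEP = 50


@dataclass
class GenomicWindow:
    """A fixed-length genomic segment with its smoothed signal and label."""

    chrom: str
    start: int
    end: int
    seq: str
    chip_score: float
    label: str  # "peak" | "nonpeak"
    accessibility: float = float("nan")
    accessible: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("window length must match sequence length")


@dataclass
class ChIPDataset:
    """Peak and non-peak windows for one TF/stage, with cached score arrays."""

    name: str
    windows: list[GenomicWindow]
    primary_motif: PWM | None = None
    stages: tuple[int, ...] = ()
    _seq_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def chip(self) -> np.ndarray:
        return np.array([w.chip_score for w in self.windows])

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows])

    @property
    def accessibility(self) -> np.ndarray:
        return np.array([w.accessibility for w in self.windows])

    @property
    def accessible(self) -> np.ndarray:
        return np.array([w.accessible for w in self.windows])

    @property
    def seq_matrix(self) -> np.ndarray:
        if self._seq_matrix is None:
            self._seq_matrix = np.vstack([encode_seq(w.seq) for w in self.windows])
        return self._seq_matrix

    def __len__(self) -> int:
        return len(self.windows)


def smooth_track(
    positions: np.ndarray,
    scores: np.ndarray,
    chrom_length: int,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Window-average a raw position->score track on a stepped grid.

    Raw positions are mapped to the nearest multiple of ``step``; each window
    ``[s, s + window)`` with ``s`` a multiple of ``step`` scores the mean of
    all mapped raw scores inside it, or 0 if none map there.
    """
    positions = np.asarray(positions, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if np.any(positions < 0):
        raise ValueError("track positions must be non-negative")
    n_grid = chrom_length // step + 1
    grid = np.minimum(np.floor(positions / step + 0.5).astype(np.int64), n_grid - 1)
    sums = np.bincount(grid, weights=scores, minlength=n_grid)
    counts = np.bincount(grid, minlength=n_grid)
    per_window = window // step
    starts = np.arange(0, max(chrom_length - window, 0) + 1, step)
    csum = np.concatenate([[0.0], np.cumsum(sums)])
    ccnt = np.concatenate([[0], np.cumsum(counts)])
    idx = starts // step
    win_sum = csum[np.minimum(idx + per_window, n_grid)] - csum[idx]
    win_cnt = ccnt[np.minimum(idx + per_window, n_grid)] - ccnt[idx]
    with np.errstate(invalid="ignore"):
        win_score = np.where(win_cnt > 0, win_sum / np.maximum(win_cnt, 1), 0.0)
    return pd.DataFrame({"start": starts, "score": win_score})


def smooth_genome(
    track: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Apply :func:`smooth_track` per chromosome; columns chrom, start, score."""
    frames = []
    for chrom, length in chrom_lengths.items():
        sub = track[track["chrom"] == chrom]
        df = smooth_track(
            sub["pos"].to_numpy(), sub["score"].to_numpy(), length, window, step
        )
        df.insert(0, "chrom", chrom)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _overlaps_any(start: int, end: int, intervals: np.ndarray) -> bool:
    """True if [start, end) overlaps any row of a sorted (n, 2) interval array."""
    if intervals.size == 0:
        return False
    i = np.searchsorted(intervals[:, 0], end)
    return bool(np.any(intervals[:i, 1] > start))


def build_dataset(
    window_scores: pd.DataFrame,
    genome: Mapping[str, str],
    exons: pd.DataFrame | None = None,
    n_peaks: int = 1000,
    n_nonpeaks: int = 1000,
    negative_mode: str = "random_noncoding",
    rng_seed: int = 0,
    nonpeak_pool: pd.DataFrame | None = None,
    name: str = "dataset",
    window: int = WINDOW,
) -> ChIPDataset:
    """Select peaks and non-peaks from smoothed window scores.

    Peaks are chosen greedily: descending score (ties by genomic coordinate),
    each selected window masking all windows overlapping it.  Non-peaks are
    drawn uniformly without replacement (seeded) from the remaining windows,
    excluding exon overlap, peak overlap and mutual overlap — or, in
    ``other_tf_peaks`` mode, from the supplied pool of other factors' peaks.
    """
    ws = window_scores.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    exon_iv: dict[str, np.ndarray] = {}
    if exons is not None and len(exons):
        for chrom, sub in exons.groupby("chrom"):
            exon_iv[chrom] = np.sort(
                sub[["start", "end"]].to_numpy(dtype=np.int64), axis=0
            )

    chosen: dict[str, list[tuple[int, int]]] = {}

    def conflicts(chrom: str, start: int) -> bool:
        return any(
            start < e and start + window > s for s, e in chosen.get(chrom, ())
        )

    def take(chrom: str, start: int) -> None:
        chosen.setdefault(chrom, []).append((start, start + window))

    peaks: list[tuple[str, int, float]] = []
    for row in ws.itertuples(index=False):
        if len(peaks) == n_peaks:
            break
        if conflicts(row.chrom, row.start):
            continue
        take(row.chrom, row.start)
        peaks.append((row.chrom, int(row.start), float(row.score)))
    if len(peaks) < n_peaks:
        raise ValueError(
            f"only {len(peaks)} non-overlapping peak windows available, need {n_peaks}"
        )

    rng = np.random.default_rng(rng_seed)
    if negative_mode == "other_tf_peaks":
        if nonpeak_pool is None:
            raise ValueError("other_tf_peaks mode requires nonpeak_pool")
        pool = nonpeak_pool.reset_index(drop=True)
    elif negative_mode == "random_noncoding":
        pool = window_scores.reset_index(drop=True)
    else:
        raise ValueError(f"unknown negative_mode {negative_mode!r}")

    order = rng.permutation(len(pool))
    nonpeaks: list[tuple[str, int, float]] = []
    for i in order:
        if len(nonpeaks) == n_nonpeaks:
            break
        row = pool.iloc[int(i)]
        chrom, start = str(row["chrom"]), int(row["start"])
        if conflicts(chrom, start):
            continue
        if _overlaps_any(start, start + window, exon_iv.get(chrom, np.empty((0, 2)))):
            continue
        take(chrom, start)
        nonpeaks.append((chrom, start, float(row["score"])))
    if len(nonpeaks) < n_nonpeaks:
        raise ValueError(
            f"only {len(nonpeaks)} eligible non-peak windows available, "
            f"need {n_nonpeaks}"
        )

    windows = [
        GenomicWindow(
            chrom=c,
            start=s,
            end=s + window,
            seq=genome[c][s : s + window],
            chip_score=score,
            label=label,
        )
        for label, rows in (("peak", peaks), ("nonpeak", nonpeaks))
        for c, s, score in rows
    ]
    return ChIPDataset(name=name, windows=windows)


def select_primary_motif(
    candidate_pwms: Sequence[PWM],
    dataset: ChIPDataset,
    model_config=None,
    folds=None,
) -> PWM:
    """Candidate with the highest cross-validated single-motif correlation.

    Ties (and a single candidate) resolve to the earliest in input order.
    """
    from .training import ModelConfig, CVFolds, cross_validate
    from .evaluation import pearson_cc

    if not candidate_pwms:
        raise ValueError("no candidate motifs supplied")
    if len(candidate_pwms) == 1:
        return candidate_pwms[0]
    config = model_config or ModelConfig(mode="single")
    folds = folds or CVFolds.stratified(dataset.labels, seed=0)
    best, best_cc = None, -np.inf
    for pwm in candidate_pwms:
        fit = cross_validate(dataset, config, folds, pwms=[pwm])
        cc = pearson_cc(fit.cv_predictions, dataset.chip)
        if cc > best_cc + 1e-12:
            best, best_cc = pwm, cc
    if best is None:
        raise RuntimeError("all candidate motifs failed to fit")
    return best


def rank_secondary_candidates(
    expression: pd.DataFrame,
    stages: Sequence,
    motif_catalog: Mapping[str, PWM],
    top_fraction: float = 0.10,
) -> list[PWM]:
    """Secondary-motif candidates by TF expression rank.

    Expression (columns ``gene``, ``stage``, ``level``) is log1p-transformed
    and z-scored within each requested stage, averaged across stages, and TFs
    with motifs are ranked by the averaged score.  Motifs of the top fraction
    are returned; catalog entries representing heterodimeric complexes (names
    containing ``::``) are excluded.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    known = set(expression["stage"].unique())
    for stage in stages:
        if stage not in known:
            raise KeyError(f"stage {stage!r} not present in expression table")
    sub = expression[expression["stage"].isin(list(stages))].copy()
    sub["logged"] = np.log1p(sub["level"])
    z = sub.groupby("stage")["logged"].transform(
        lambda v: (v - v.mean()) / (v.std(ddof=0) or 1.0)
    )
    sub["z"] = z
    ranking = (
        sub.groupby("gene", sort=False)["z"].mean().sort_values(
            ascending=False, kind="mergesort"
        )
    )
    eligible = [
        g for g in ranking.index if g in motif_catalog and "::" not in g
    ]
    n_take = int(len(eligible) * top_fraction + 1e-9)
    return [motif_catalog[g] for g in eligible[:n_take]]


def attach_accessibility(
    dataset: ChIPDataset,
    accessibility_track: pd.DataFrame,
    percentile: float = 90.0,
    step: int = STEP,
) -> ChIPDataset:
    """Attach smoothed accessibility and flag accessible windows in place.

    Accessibility is smoothed with the same mapping as the ChIP signal (raw
    positions to the nearest multiple of ``step``, window mean).  A window is
    accessible iff its score is >= the given percentile over all dataset
    windows (ties at the threshold included).  Windows with no coverage score
    0 and are flagged inaccessible.
    """
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in accessibility_track.groupby("chrom"):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if np.any(pos < 0):
            raise ValueError("track positions must be non-negative")
        grid = np.floor(pos / step + 0.5).astype(np.int64)
        n = int(grid.max()) + 1 if grid.size else 1
        sums = np.bincount(grid, weights=sub["score"].to_numpy(), minlength=n)
        counts = np.bincount(grid, minlength=n)
        per_chrom[chrom] = (sums, counts, np.array([n]))

    values = np.zeros(len(dataset))
    covered = np.zeros(len(dataset), dtype=bool)
    for i, w in enumerate(dataset.windows):
        entry = per_chrom.get(w.chrom)
        if entry is None:
            continue
        sums, counts, nmax = entry
        lo, hi = w.start // step, min(-(-w.end // step), int(nmax[0]))
        cnt = counts[lo:hi].sum()
        if cnt > 0:
            values[i] = sums[lo:hi].sum() / cnt
            covered[i] = True
    threshold = np.percentile(values, percentile)
    for w, v, c in zip(dataset.windows, values, covered):
        w.accessibility = float(v)
        w.accessible = bool(c and v >= threshold)
    return dataset


# -- plain-text I/O --------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """0-based half-open intervals; columns chrom, start, end."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
    )


def read_track(path: str | Path) -> pd.DataFrame:
    """bedGraph (chrom start end score -> position=start) or chrom pos score TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 4:
        return pd.DataFrame(
            {"chrom": df[0], "pos": df[1].astype(int), "score": df[3].astype(float)}
        )
    return pd.DataFrame(
        {"chrom": df[0], "pos": df[1].astype(int), "score": df[2].astype(float)}
    )


def write_dataset(dataset: ChIPDataset, out_prefix: str | Path) -> None:
    """TSV of window metadata plus a FASTA of window sequences."""
    prefix = Path(out_prefix)
    rows = [
        {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "label": w.label,
            "chip": w.chip_score,
            "accessibility": w.accessibility,
        }
        for w in dataset.windows
    ]
    pd.DataFrame(rows).to_csv(f"{prefix}.tsv", sep="\t", index=False)
    write_fasta(
        {f"{w.chrom}:{w.start}-{w.end}": w.seq for w in dataset.windows},
        f"{prefix}.fa",
    )
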