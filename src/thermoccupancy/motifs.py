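"""Position weight matrices, log-likelihood-ratio site scanning and motif shuffling.

A PWM stores per-position base probabilities for a transcription factor's
binding specificity.  Sites are scored by the log-likelihood ratio (LLR)
against a background composition, in natural-log units so that the
thermodynamic occupancy model can exponentiate scores directly into relative
affinities ``exp(LLR - LLR_max)``.  Information content is reported in bits,
as is conventional.

Two site-inclusion criteria are supported when scanning:

* a relative-affinity floor (default 0.01 of the consensus site), used by the
  occupancy model, and
* an exact p-value threshold under the background model (e.g. ``e**-7``,
  mimicking a FIMO scan), used by the inter-site spacing analyses.  The null
  score distribution is computed by exact dynamic programming over a
  discretized LLR grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PWM",
    "Site",
    "encode_seq",
    "decode_seq",
    "revcomp",
    "llr_score",
    "scan_sites",
    "scan_encoded",
    "shuffle_pwm",
    "information_content",
    "llr_threshold_for_pvalue",
    "read_meme_minimal",
    "write_meme_minimal",
    "read_pwm_tsv",
]

BASES = "ACGT"
UNIFORM_BG = np.full(4, 0.25)

_ENCODING = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODING[ord(_b)] = _i
    _ENCODING[ord(_b.lower())] = _i

# Sentinel additive score for ambiguous (non-ACGT) bases: any site touching an
# ambiguous base scores far below every realizable threshold and is dropped.
_AMBIG_SCORE = -1e30


def encode_seq(seq: str) -> np.ndarray:
    """Encode a base string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODING[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


@dataclass
class PWM:
    """Base-probability matrix of length L with a background composition.

    ``probs`` has shape (L, 4), one row per position.  A pseudocount floor is
    mixed in at construction and rows are renormalized, so every stored entry
    is strictly positive and log-ratios are finite.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must have shape (L, 4) with L >= 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("each column must have positive total probability")
        probs = probs / sums[:, None]
        if self.pseudocount:
            probs = (probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        self.probs = probs
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        self.background = bg
        self._llr: np.ndarray | None = None

    # -- derived quantities ------------------------------------------------

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def llr(self) -> np.ndarray:
        """Per-position natural-log likelihood ratios, shape (L, 4)."""
        if self._llr is None:
            self._llr = np.log(self.probs) - np.log(self.background)[None, :]
        return self._llr

    @property
    def llr_max(self) -> float:
        """LLR of the consensus (strongest attainable) site."""
        return float(self.llr.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.llr.argmax(axis=1))

    def without_pseudocount(self, name: str | None = None, probs: np.ndarray | None = None) -> "PWM":
        """Clone with already-adjusted probabilities (no second pseudocount)."""
        return PWM(
            name=self.name if name is None else name,
            probs=self.probs if probs is None else probs,
            background=self.background,
            pseudocount=0.0,
        )


@dataclass(frozen=True)
class Site:
    """A located, stranded motif match.

    ``rel_affinity = exp(llr - llr_max)`` lies in (0, 1] and equals 1 exactly
    for a consensus match.
    """

    motif: str
    start: int
    end: int
    strand: str
    llr: float
    rel_affinity: float


def llr_score(pwm: PWM, kmer: str, strand: str = "+") -> float:
    """Natural-log likelihood ratio of ``kmer`` on the given strand.

    On the minus strand the reverse complement of the k-mer is scored.
    Raises on length mismatch or non-ACGT symbols.
    """
    if len(kmer) != pwm.length:
        raise ValueError(f"k-mer length {len(kmer)} != motif length {pwm.length}")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if strand == "-":
        kmer = revcomp(kmer)
    codes = encode_seq(kmer)
    if np.any(codes > 3):
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    return float(pwm.llr[np.arange(pwm.length), codes].sum())


def _llr5(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-strand scoring tables over the 5-letter alphabet."""
    L = pwm.length
    fwd = np.full((L, 5), _AMBIG_SCORE)
    fwd[:, :4] = pwm.llr
    rev = np.full((L, 5), _AMBIG_SCORE)
    rev[:, :4] = pwm.llr[::-1, ::-1]
    return fwd, rev


def position_scores(pwm: PWM, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LLR at every start position on both strands of encoded sequences.

    ``enc`` is a (n_seq, W) uint8 matrix; returns two (n_seq, W-L+1) arrays
    (forward, reverse).  Positions touching ambiguous bases score far below
    any threshold.
    """
    if enc.ndim == 1:
        enc = enc[None, :]
    L = pwm.length
    W = enc.shape[1]
    if W < L:
        return (np.empty((enc.shape[0], 0)), np.empty((enc.shape[0], 0)))
    P = W - L + 1
    fwd_tab, rev_tab = _llr5(pwm)
    fwd = np.zeros((enc.shape[0], P))
    rev = np.zeros((enc.shape[0], P))
    for l in range(L):
        block = enc[:, l : l + P]
        fwd += fwd_tab[l][block]
        rev += rev_tab[l][block]
    return fwd, rev


def _resolve_threshold(
    pwm: PWM,
    min_rel_affinity: float | None,
    pvalue_threshold: float | None,
) -> float:
    if (min_rel_affinity is None) == (pvalue_threshold is None):
        raise ValueError("specify exactly one of min_rel_affinity or pvalue_threshold")
    if min_rel_affinity is not None:
        if min_rel_affinity < 0:
            raise ValueError("min_rel_affinity must be >= 0")
        if min_rel_affinity == 0:
            # keep every ACGT position while still excluding ambiguous bases
            return _AMBIG_SCORE * 1e-2
        return pwm.llr_max + math.log(min_rel_affinity)
    return llr_threshold_for_pvalue(pwm, pvalue_threshold)


def scan_encoded(
    pwm: PWM,
    enc: np.ndarray,
    llr_threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scan encoded sequences; returns (seq_idx, start, strand_code, llr).

    strand_code 0 = forward, 1 = reverse.  Both strands are scanned at every
    start position; scores >= threshold are kept.
    """
    fwd, rev = position_scores(pwm, enc)
    iw_f, pos_f = np.nonzero(fwd >= llr_threshold)
    iw_r, pos_r = np.nonzero(rev >= llr_threshold)
    seq_idx = np.concatenate([iw_f, iw_r])
    start = np.concatenate([pos_f, pos_r])
    strand = np.concatenate(
        [np.zeros(iw_f.size, dtype=np.int8), np.ones(iw_r.size, dtype=np.int8)]
    )
    llr = np.concatenate([fwd[iw_f, pos_f], rev[iw_r, pos_r]])
    order = np.lexsort((strand, start, seq_idx))
    return seq_idx[order], start[order], strand[order], llr[order]


def scan_sites(
    pwm: PWM,
    seq: str,
    min_rel_affinity: float | None = None,
    pvalue_threshold: float | None = None,
) -> list[Site]:
    """All sites of ``pwm`` in ``seq`` passing the chosen criterion.

    Sites are returned sorted by start position (forward strand first at equal
    starts).  Sites overlapping ambiguous bases are excluded.  An empty or
    too-short sequence yields an empty list.
    """
    if len(seq) < pwm.length:
        return []
    thr = _resolve_threshold(pwm, min_rel_affinity, pvalue_threshold)
    enc = encode_seq(seq)[None, :]
    _, start, strand, llr = scan_encoded(pwm, enc, thr)
    lmax = pwm.llr_max
    return [
        Site(
            motif=pwm.name,
            start=int(s),
            end=int(s) + pwm.length,
            strand="+-"[int(st)],
            llr=float(v),
            rel_affinity=float(np.exp(min(v - lmax, 0.0))),
        )
        for s, st, v in zip(start, strand, llr)
    ]


def shuffle_pwm(pwm: PWM, rng_seed: int | np.random.Generator) -> PWM:
    """Random row (base-label) and column (position) permutation of a PWM.

    Preserves the multiset of column probability vectors up to base
    relabeling, hence the total information content (for the uniform
    background used throughout).
    """
    rng = np.random.default_rng(rng_seed)
    row_perm = rng.permutation(4)
    col_perm = rng.permutation(pwm.length)
    shuffled = pwm.probs[col_perm][:, row_perm]
    return pwm.without_pseudocount(name=f"{pwm.name}_shuf", probs=shuffled)


def information_content(pwm: PWM) -> float:
    """Total information content in bits: sum over positions of KL(p || bg)."""
    return float((pwm.probs * np.log2(pwm.probs / pwm.background[None, :])).sum())


def llr_threshold_for_pvalue(
    pwm: PWM, pvalue: float, precision: float = 1e-4
) -> float:
    """Smallest LLR threshold with a background tail probability <= ``pvalue``.

    The null distribution of the single-strand LLR score of a random k-mer
    drawn from the background is computed exactly by dynamic programming over
    a discretized score grid (grid step ``precision`` natural-log units).  A
    safety margin of one grid step per position is added so discretization
    can only make the threshold more stringent, never more permissive.
    """
    if not 0 < pvalue < 1:
        raise ValueError("pvalue must be in (0, 1)")
    cache = getattr(pwm, "_pvalue_cache", None)
    if cache is None:
        cache = {}
        pwm._pvalue_cache = cache
    key = (pvalue, precision)
    if key in cache:
        return cache[key]
    iscores = np.round(pwm.llr / precision).astype(np.int64)
    mins = iscores.min(axis=1)
    span = int((iscores.max(axis=1) - mins).sum())
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    offset = 0
    for l in range(pwm.length):
        width = int(iscores[l].max() - mins[l])
        nxt = np.zeros(span + 1)
        for b in range(4):
            shift = int(iscores[l, b] - mins[l])
            if pwm.background[b] > 0:
                nxt[shift : shift + offset + 1] += pwm.background[b] * dist[: offset + 1]
        dist = nxt
        offset += width
    sf = np.cumsum(dist[::-1])[::-1]
    passing = np.nonzero(sf <= pvalue)[0]
    if passing.size == 0:
        # no realizable score is rare enough; threshold just above the maximum
        result = pwm.llr_max + precision
    else:
        t = int(passing[0])
        result = float((t + mins.sum()) * precision) + pwm.length * precision
    cache[key] = result
    return result


# -- file formats ----------------------------------------------------------


def read_meme_minimal(path: str | Path) -> list[PWM]:
    """Read motifs from MEME-minimal-style text (ACGT alphabet).

    Only the ``MOTIF`` and ``letter-probability matrix`` records are
    interpreted; background defaults to uniform unless a ``Background letter
    frequencies`` line is present.
    """
    pwms: list[PWM] = []
    bg = UNIFORM_BG.copy()
    name: str | None = None
    rows: list[list[float]] = []
    expect_bg = False

    def flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            pwms.append(PWM(name=name, probs=np.array(rows), background=bg.copy()))
        name, rows = None, []

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if expect_bg:
            parts = line.split()
            freqs = {parts[i]: float(parts[i + 1]) for i in range(0, len(parts) - 1, 2)}
            bg = np.array([freqs.get(b, 0.25) for b in BASES])
            bg = bg / bg.sum()
            expect_bg = False
            continue
        if line.startswith("Background letter frequencies"):
            expect_bg = True
        elif line.startswith("MOTIF"):
            flush()
            name = line.split()[1]
        elif line.startswith("letter-probability"):
            continue
        elif name is not None and line and (line[0].isdigit() or line[0] == "."):
            rows.append([float(x) for x in line.split()[:4]])
    flush()
    return pwms


def write_meme_minimal(pwms: Iterable[PWM], path: str | Path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", ""]
    first = True
    for pwm in pwms:
        if first:
            bg = pwm.background
            lines.append(
                "Background letter frequencies"
            )
            lines.append(
                " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg))
            )
            lines.append("")
            first = False
        lines.append(f"MOTIF {pwm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.length}"
        )
        for row in pwm.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwm_tsv(path: str | Path, name: str | None = None) -> PWM:
    """Read a plain 4xL (rows A,C,G,T) or Lx4 tab-separated probability matrix."""
    rows = [
        [float(x) for x in line.split()]
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    mat = np.array(rows)
    if mat.shape[0] == 4 and mat.shape[1] != 4:
        mat = mat.T
    return PWM(name=name or Path(path).stem, probs=mat)
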