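import math

import numpy as np
import pytest

from thermoccupancy.motifs import PWM, Site


def make_site(
    motif: str, start: int, length: int, rel_affinity: float, strand: str = "+"
) -> Site:
    """Site with a given relative affinity (llr set consistently below max)."""
    return Site(
        motif=motif,
        start=start,
        end=start + length,
        strand=strand,
        llr=math.log(rel_affinity),
        rel_affinity=rel_affinity,
    )


def random_sites(
    rng: np.random.Generator,
    n: int,
    motif_names: tuple[str, ...] = ("M1", "M2"),
    span: int = 200,
) -> list[Site]:
    """Random candidate sites, possibly overlapping, for oracle comparisons."""
    sites = []
    for _ in range(n):
        length = int(rng.integers(5, 11))
        start = int(rng.integers(0, span - length))
        motif = motif_names[int(rng.integers(0, len(motif_names)))]
        rel = float(rng.uniform(0.05, 1.0))
        strand = "+-"[int(rng.integers(0, 2))]
        sites.append(make_site(motif, start, length, rel, strand))
    return sorted(sites, key=lambda s: (s.start, s.end, s.strand))


@pytest.fixture
def sharp_pwm_pair() -> tuple[PWM, PWM]:
    """Two near-one-hot motifs with distinct non-palindromic consensi."""

    def sharp(name: str, consensus: str) -> PWM:
        probs = np.full((len(consensus), 4), 0.01 / 3)
        for i, b in enumerate(consensus):
            probs[i, "ACGT".index(b)] = 0.99
        return PWM(name=name, probs=probs)

    return sharp("M1", "GGATGC"), sharp("M2", "TTGCCA")
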