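"""Numba kernels for the occupancy dynamic program.

The expected bound-site count of the primary factor is a ratio of partition
sums over all non-overlapping subsets of candidate sites.  The DP scans sites
in coordinate order and conditions on the last bound site; because bound
sites never overlap, coordinate order is well defined within a configuration,
and the pairwise interaction term (applied between adjacent bound
heterotypic sites separated by at most d_T) factorizes over the chain.

Accumulators are kept in linear space and rescaled in place whenever they
grow past 1e250, which keeps the ratio exact while avoiding overflow at
large gamma.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_RESCALE_AT = 1e250
_RESCALE_BY = 1e-250


@njit(cache=True)
def occ_batch(ptr, starts, ends, motif_ids, relaff, gamma0, gamma1, omega, d_t, out):
    """Expected bound primary-site count per window.

    Sites are concatenated over windows in CSR layout (``ptr``), sorted by
    start within each window.  ``motif_ids`` holds 0 for the primary motif and
    1 for the secondary; the interaction term ``omega`` applies between
    adjacent bound heterotypic pairs with gap (start - previous end) in
    [0, d_t].
    """
    n_windows = ptr.size - 1
    for w in range(n_windows):
        lo = ptr[w]
        n = ptr[w + 1] - lo
        if n == 0:
            out[w] = 0.0
            continue
        z = np.empty(n)
        nacc = np.empty(n)
        z_empty = 1.0
        for ii in range(n):
            i = lo + ii
            g = gamma0 if motif_ids[i] == 0 else gamma1
            q = g * relaff[i]
            si = starts[i]
            zi = z_empty
            ni = 0.0
            for jj in range(ii):
                j = lo + jj
                if ends[j] <= si:
                    a = 1.0
                    if motif_ids[j] != motif_ids[i] and si - ends[j] <= d_t:
                        a = omega
                    zi += a * z[jj]
                    ni += a * nacc[jj]
            is_primary = 1.0 if motif_ids[i] == 0 else 0.0
            z[ii] = q * zi
            nacc[ii] = q * (ni + is_primary * zi)
            if z[ii] > _RESCALE_AT or nacc[ii] > _RESCALE_AT:
                for k in range(ii + 1):
                    z[k] *= _RESCALE_BY
                    nacc[k] *= _RESCALE_BY
                z_empty *= _RESCALE_BY
        total_z = z_empty
        total_n = 0.0
        for ii in range(n):
            total_z += z[ii]
            total_n += nacc[ii]
        out[w] = total_n / total_z
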