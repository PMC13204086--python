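"""Independent brute-force gamma oracle shared by the metric and
acceptance suites: naive per-point exhaustive search over the same
sub-voxel lattice the implementation uses."""

import numpy as np
from scipy.ndimage import map_coordinates


def exhaustive_gamma(ref, ev, spacing, dd_pct, dta, thr_pct, subsample, factor):
    ref_max = ref.max()
    dd = dd_pct / 100.0 * ref_max
    radius = factor * dta
    steps = spacing / subsample
    nshift = int(radius // steps)
    out = np.full(ref.shape, np.nan)
    for idx in np.ndindex(ref.shape):
        if ref[idx] < thr_pct / 100.0 * ref_max:
            continue
        best = np.inf
        for sx in range(-nshift, nshift + 1):
            for sy in range(-nshift, nshift + 1):
                for sz in range(-nshift, nshift + 1):
                    d2 = (sx**2 + sy**2 + sz**2) * steps**2
                    if d2 > radius**2:
                        continue
                    coord = np.array(
                        [[idx[0] + sx / subsample],
                         [idx[1] + sy / subsample],
                         [idx[2] + sz / subsample]]
                    )
                    val = map_coordinates(ev, coord, order=1, mode="nearest")[0]
                    g2 = (val - ref[idx]) ** 2 / dd**2 + d2 / dta**2
                    best = min(best, g2)
        out[idx] = np.sqrt(best)
    return out
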