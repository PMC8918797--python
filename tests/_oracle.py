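"""Independent reference implementations used only by the tests.

These deliberately avoid the library's FFT/vectorised code paths: the ACF
oracle is a shift-by-shift direct double sum, and the t-test oracle is the
textbook pooled-variance formula.
"""

import numpy as np
from scipy.stats import t as t_dist


def direct_masked_acf(plane, mask):
    """O(n^4)-style direct evaluation of the masked ACF.

    C(d) = sum over in-mask pairs of (I - mean)(I' - mean) / (N(d) var),
    with mean/var over the mask.  Returns (corr, counts) centred at zero
    shift; shifts with no pairs are NaN.
    """
    plane = np.asarray(plane, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = plane[mask]
    mu, var = vals.mean(), vals.var()
    ny, nx = plane.shape
    corr = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    counts = np.zeros((2 * ny - 1, 2 * nx - 1), dtype=int)
    for dy in range(-(ny - 1), ny):
        for dx in range(-(nx - 1), nx):
            s = 0.0
            n = 0
            for y in range(ny):
                for x in range(nx):
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < ny and 0 <= x2 < nx and mask[y, x] and mask[y2, x2]:
                        s += (plane[y, x] - mu) * (plane[y2, x2] - mu)
                        n += 1
            counts[dy + ny - 1, dx + nx - 1] = n
            if n:
                corr[dy + ny - 1, dx + nx - 1] = s / (n * var)
    return corr, counts


def pooled_t_two_tailed(a, b):
    """Textbook two-sample pooled-variance Student's t and two-tailed p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * t_dist.sf(abs(t), df)
    return t, p, df
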