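"""Independent reference implementations used as test oracles."""

import numpy as np


def brute_kuiper(angles, weights, lo, hi):
    """Sup-norm evaluation of the Kuiper deviations against uniform.

    Evaluates ECDF - F on a dense grid plus every jump point, with the
    right-continuous ECDF for d1 and its left limit for d2, via
    searchsorted on the sorted sample (independent of the implementation's
    unique/bincount path).
    """
    angles = np.asarray(angles, float)
    weights = np.asarray(weights, float)
    order = np.argsort(angles)
    a, cw = angles[order], np.cumsum(weights[order])
    W = cw[-1]
    pts = np.unique(np.concatenate([np.linspace(lo, hi, 1501), angles]))
    idx_r = np.searchsorted(a, pts, side="right")
    idx_l = np.searchsorted(a, pts, side="left")
    ec_r = np.where(idx_r > 0, cw[np.maximum(idx_r - 1, 0)], 0.0) / W
    ec_l = np.where(idx_l > 0, cw[np.maximum(idx_l - 1, 0)], 0.0) / W
    F = (pts - lo) / (hi - lo)
    return max((ec_r - F).max(), 0.0), max((F - ec_l).max(), 0.0)
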