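"""Independent oracles used by the test-suite (kept separate from the code
paths they check)."""

import numpy as np
from scipy.optimize import minimize

from tgnet.fitter import _QuadLoss, _offdiag_mask


def smoothed_objective(mats, cfg, tie_offdiag=False, eps=1e-9):
    """Independent solution of the penalized joint objective: L-BFGS on an
    epsilon-smoothed surrogate (|x| -> sqrt(x^2+eps), Frobenius norm ->
    sqrt(sum^2+eps)).  With ``tie_offdiag`` the off-diagonals are shared
    across all periods (the fusion limit), diagonals and eta per-period.
    """
    p = mats[0].shape[1]
    M = len(mats)
    k = p * (p + 1) // 2 + p
    off = _offdiag_mask(p)
    losses = [_QuadLoss(Y, cfg.hweight) for Y in mats]

    if tie_offdiag:
        n_off = int(off.sum())
        n_other = k - n_off

        def unstack(vec):
            shared = vec[:n_off]
            out = []
            for m in range(M):
                x = np.zeros(k)
                x[off] = shared
                x[~off] = vec[n_off + m * n_other : n_off + (m + 1) * n_other]
                out.append(x)
            return out

        dim = n_off + M * n_other
    else:

        def unstack(vec):
            return [vec[m * k : (m + 1) * k] for m in range(M)]

        dim = M * k

    def f(vec, smooth=eps):
        X = unstack(vec)
        val = 0.0
        for m in range(M):
            val += losses[m].value(X[m])
            val += cfg.lambda1 * 2 * np.sum(np.sqrt(X[m][off] ** 2 + smooth))
        for m in range(M - 1):
            diff = X[m][off] - X[m + 1][off]
            val += cfg.lambda2 * np.sqrt(2 * np.sum(diff**2) + smooth)
        return val

    res = minimize(
        f,
        np.zeros(dim),
        method="L-BFGS-B",
        options={"maxiter": 30000, "ftol": 1e-15, "gtol": 1e-12},
    )
    # report the exact (unsmoothed) objective at the smoothed minimizer so
    # the smoothing constants do not bias the comparison
    return f(res.x, smooth=0.0)
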