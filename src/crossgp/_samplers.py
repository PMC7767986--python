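"""Numba kernels for the mixture-prior SNP model (EM sweep + Gibbs chain).

These are internal hot loops; the public surface lives in ``bayesr``. All
randomness goes through numba's own np.random state, seeded at kernel entry,
so a chain is a pure function of its arguments.
"""
import numpy as np
from numba import njit

NCOMP = 4


@njit(cache=True)
def _weighted_col_sq(Wt, w):
    m, n = Wt.shape
    out = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += w[i] * Wt[j, i] * Wt[j, i]
        out[j] = s
    return out


@njit(cache=True)
def em_sweeps(y, Wt, X, w, log_pi, sigma2_k, sigma2_e, XtDX_inv,
              tol, max_iter):
    """Conditional-expectation sweeps over SNPs until max |delta v| < tol.

    Returns (v, gamma, b, n_sweeps, flag) with flag 0 = converged,
    1 = hit max_iter, 2 = diverged (effect norm grew 10x over 50 sweeps).
    """
    m, n = Wt.shape
    p = X.shape[1]
    v = np.zeros(m)
    gamma = np.zeros((m, NCOMP))
    Cj = _weighted_col_sq(Wt, w)
    # start from the weighted least-squares fixed effects
    rhs_b = np.zeros(p)
    for i in range(n):
        wy = w[i] * y[i]
        for q in range(p):
            rhs_b[q] += X[i, q] * wy
    b = XtDX_inv @ rhs_b
    r = y - X @ b
    lg = np.empty(NCOMP)
    norms = np.zeros(50)
    flag = 1
    sweeps = 0
    for sweep in range(max_iter):
        sweeps = sweep + 1
        max_delta = 0.0
        for j in range(m):
            if Cj[j] <= 0.0:
                continue
            vj = v[j]
            rhs = Cj[j] * vj
            for i in range(n):
                rhs += w[i] * Wt[j, i] * r[i]
            r_ls = rhs / Cj[j]
            var_ls = sigma2_e / Cj[j]
            maxlp = -1e300
            for k in range(NCOMP):
                s2 = sigma2_k[k] + var_ls
                lg[k] = log_pi[k] - 0.5 * np.log(s2) - 0.5 * r_ls * r_ls / s2
                if lg[k] > maxlp:
                    maxlp = lg[k]
            tot = 0.0
            for k in range(NCOMP):
                lg[k] = np.exp(lg[k] - maxlp)
                tot += lg[k]
            v_new = 0.0
            for k in range(NCOMP):
                g = lg[k] / tot
                gamma[j, k] = g
                if sigma2_k[k] > 0.0:
                    var_post = 1.0 / (Cj[j] / sigma2_e + 1.0 / sigma2_k[k])
                    v_new += g * var_post * rhs / sigma2_e
            d = v_new - vj
            if d != 0.0:
                for i in range(n):
                    r[i] -= Wt[j, i] * d
                v[j] = v_new
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
        # refresh fixed effects given current SNP effects
        rb = r + X @ b
        for q in range(p):
            rhs_b[q] = 0.0
        for i in range(n):
            wy = w[i] * rb[i]
            for q in range(p):
                rhs_b[q] += X[i, q] * wy
        b_new = XtDX_inv @ rhs_b
        r = rb - X @ b_new
        b = b_new
        # divergence guard on the effect-vector norm
        nv = 0.0
        for j in range(m):
            nv += v[j] * v[j]
        nv = np.sqrt(nv)
        if sweep >= 50 and norms[sweep % 50] > 0.0 and nv > 10.0 * norms[sweep % 50]:
            flag = 2
            break
        norms[sweep % 50] = nv
        if max_delta < tol:
            flag = 0
            break
    return v, gamma, b, sweeps, flag


@njit(cache=True)
def gibbs_chain(y, Wt, X, w, log_pi, sigma2_k, sigma2_e, XtDX_inv, Lb,
                iters, burnin, seed, v_init, b_init):
    """Single-site Gibbs over component indicators and SNP effects.

    Per iteration: sample b from its weighted least-squares conditional
    (flat prior; Lb is the Cholesky factor of XtDX_inv * sigma2_e), then visit
    SNPs in a freshly shuffled order, sampling the 4-way component indicator
    and the effect from its conditional normal (component 0 forces zero).
    Returns post-burnin means of v, component probabilities, b, and an error
    iteration (-1 if the residual stayed finite).
    """
    np.random.seed(seed)
    m, n = Wt.shape
    p = X.shape[1]
    v = v_init.copy()
    b = b_init.copy()
    r = y - X @ b
    for j in range(m):
        if v[j] != 0.0:
            for i in range(n):
                r[i] -= Wt[j, i] * v[j]
    Cj = _weighted_col_sq(Wt, w)
    v_sum = np.zeros(m)
    b_sum = np.zeros(p)
    comp_counts = np.zeros((m, NCOMP))
    order = np.arange(m)
    lg = np.empty(NCOMP)
    kept = 0
    err_iter = -1
    for it in range(iters):
        # ---- fixed effects
        rb = r + X @ b
        rhs_b = np.zeros(p)
        for i in range(n):
            wy = w[i] * rb[i]
            for q in range(p):
                rhs_b[q] += X[i, q] * wy
        b_hat = XtDX_inv @ rhs_b
        z = np.empty(p)
        for q in range(p):
            z[q] = np.random.standard_normal()
        b = b_hat + Lb @ z
        r = rb - X @ b
        # ---- fresh SNP visit order
        for j in range(m - 1, 0, -1):
            k = np.random.randint(0, j + 1)
            tmp = order[j]
            order[j] = order[k]
            order[k] = tmp
        # ---- SNP updates
        for t in range(m):
            j = order[t]
            if Cj[j] <= 0.0:
                continue
            vj = v[j]
            rhs = Cj[j] * vj
            for i in range(n):
                rhs += w[i] * Wt[j, i] * r[i]
            r_ls = rhs / Cj[j]
            var_ls = sigma2_e / Cj[j]
            maxlp = -1e300
            for k in range(NCOMP):
                s2 = sigma2_k[k] + var_ls
                lg[k] = log_pi[k] - 0.5 * np.log(s2) - 0.5 * r_ls * r_ls / s2
                if lg[k] > maxlp:
                    maxlp = lg[k]
            tot = 0.0
            for k in range(NCOMP):
                lg[k] = np.exp(lg[k] - maxlp)
                tot += lg[k]
            u = np.random.random() * tot
            comp = NCOMP - 1
            acc = 0.0
            for k in range(NCOMP):
                acc += lg[k]
                if u <= acc:
                    comp = k
                    break
            if sigma2_k[comp] <= 0.0:
                v_new = 0.0
            else:
                var_post = 1.0 / (Cj[j] / sigma2_e + 1.0 / sigma2_k[comp])
                mean_post = var_post * rhs / sigma2_e
                v_new = mean_post + np.sqrt(var_post) * np.random.standard_normal()
            d = v_new - vj
            if d != 0.0:
                for i in range(n):
                    r[i] -= Wt[j, i] * d
                v[j] = v_new
            if it >= burnin:
                comp_counts[j, comp] += 1.0
        # ---- bookkeeping
        rsum = 0.0
        for i in range(n):
            rsum += r[i]
        if not np.isfinite(rsum):
            err_iter = it
            break
        if it >= burnin:
            kept += 1
            for j in range(m):
                v_sum[j] += v[j]
            for q in range(p):
                b_sum[q] += b[q]
    if kept > 0:
        v_sum /= kept
        b_sum /= kept
        comp_counts /= kept
    return v_sum, comp_counts, b_sum, err_iter
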