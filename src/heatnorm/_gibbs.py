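"""Numba kernels for the Gibbs sampler of the reaction-norm animal model.

The sampler works on a precomputed union sparsity pattern of the mixed-model
coefficient matrix.  Per iteration it (1) refreshes the coefficient-matrix
values from the current residual variances and the inverses of the sampled
6x6 additive and permanent-environment covariance matrices, (2) samples
location effects -- fixed effects scalar-wise, animal coefficient 6-vectors
as joint blocks from their full conditionals, (3) samples the six residual
variances from scaled inverse chi-square full conditionals, and (4) samples
the joint covariance matrices from inverse-Wishart full conditionals.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chol(A, L):
    """Lower Cholesky of SPD A into L; returns False if not positive definite."""
    p = A.shape[0]
    for i in range(p):
        for j in range(p):
            L[i, j] = 0.0
    for i in range(p):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _chol_solve(L, b, x):
    """Solve (L L') x = b given lower-triangular L."""
    p = L.shape[0]
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(p - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True)
def _spd_inv(A, out):
    """Inverse of SPD A via Cholesky, escalating diagonal jitter if needed."""
    p = A.shape[0]
    L = np.zeros((p, p))
    B = A.copy()
    eps = 0.0
    tr = 0.0
    for i in range(p):
        tr += A[i, i]
    for _ in range(8):
        if _chol(B, L):
            break
        eps = 1e-10 * tr if eps == 0.0 else eps * 100.0
        for i in range(p):
            B[i, i] = A[i, i] + eps
    b = np.zeros(p)
    x = np.zeros(p)
    for j in range(p):
        for i in range(p):
            b[i] = 1.0 if i == j else 0.0
        _chol_solve(L, b, x)
        for i in range(p):
            out[i, j] = x[i]


@njit(cache=True)
def _inv_wishart(df, S, out):
    """Draw out ~ InvWishart(df, scale S) via the Bartlett decomposition."""
    p = S.shape[0]
    Sinv = np.zeros((p, p))
    _spd_inv(S, Sinv)
    Lp = np.zeros((p, p))
    ok = _chol(Sinv, Lp)
    if not ok:
        _spd_inv(Sinv, Sinv)  # unreachable in practice; keeps kernel total
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.normal()
    F = Lp @ A
    W = F @ F.T
    _spd_inv(W, out)


@njit(cache=True)
def find_positions(indptr, indices, rows, cols, out):
    """Positions of (rows[t], cols[t]) entries inside a sorted CSR pattern."""
    for t in range(rows.shape[0]):
        i = rows[t]
        j = cols[t]
        lo = indptr[i]
        hi = indptr[i + 1]
        while lo < hi:
            mid = (lo + hi) // 2
            if indices[mid] < j:
                lo = mid + 1
            else:
                hi = mid
        out[t] = lo


@njit(cache=True)
def run_chain(
    indptr,
    indices,
    m_pos,
    m_val,
    m_seg,
    rhs_cls,
    ap_pos,
    ap_k,
    ap_r,
    ap_c,
    ainv_val,
    ainv_i,
    ainv_j,
    pp_pos,
    pp_r,
    pp_c,
    w_indptr,
    w_indices,
    w_data,
    y,
    rclass,
    n_fixed,
    n_ped,
    n_rec,
    Sa0,
    nu_a,
    Sp0,
    nu_p,
    se0,
    nu_e,
    Lk,
    k_indptr,
    k_indices,
    k_data,
    rec_ped,
    length,
    burnin,
    thin,
    seed,
    out_G,
    out_P,
    out_s,
    theta_mean,
):
    np.random.seed(seed)
    ncoef = n_fixed + 6 * n_ped + 6 * n_rec
    nnzU = indices.shape[0]
    theta = np.zeros(ncoef)
    G0 = Sa0.copy()
    P0 = Sp0.copy()
    sig = se0.copy()
    G0inv = np.zeros((6, 6))
    P0inv = np.zeros((6, 6))
    invsig = np.zeros(6)
    dataU = np.zeros(nnzU)
    rhs = np.zeros(ncoef)
    Cblk = np.zeros((6, 6))
    Lblk = np.zeros((6, 6))
    bvec = np.zeros(6)
    mvec = np.zeros(6)
    zvec = np.zeros(6)
    xvec = np.zeros(6)
    Sa = np.zeros((6, 6))
    Sp = np.zeros((6, 6))
    Sscale = np.zeros((6, 6))
    sse = np.zeros(6)
    swap_mu = np.zeros(n_ped)
    swap_s = np.zeros(n_ped)
    swap_z = np.zeros(n_ped)
    svec6 = np.zeros(6)
    vvec6 = np.zeros(6)
    nclass = np.zeros(6)
    for m in range(rclass.shape[0]):
        nclass[rclass[m]] += 1.0
    a_off = n_fixed
    p_off = n_fixed + 6 * n_ped
    kept = 0
    for it in range(1, length + 1):
        _spd_inv(G0, G0inv)
        _spd_inv(P0, P0inv)
        for o in range(6):
            invsig[o] = 1.0 / sig[o]
        # ---- assemble coefficient matrix values on the union pattern ----
        for t in range(nnzU):
            dataU[t] = 0.0
        for o in range(6):
            w = invsig[o]
            for t in range(m_seg[o], m_seg[o + 1]):
                dataU[m_pos[t]] += w * m_val[t]
        for t in range(ap_pos.shape[0]):
            dataU[ap_pos[t]] += ainv_val[ap_k[t]] * G0inv[ap_r[t], ap_c[t]]
        for t in range(pp_pos.shape[0]):
            dataU[pp_pos[t]] += P0inv[pp_r[t], pp_c[t]]
        for i in range(ncoef):
            s = 0.0
            for o in range(6):
                s += invsig[o] * rhs_cls[o, i]
            rhs[i] = s
        # ---- fixed effects: scalar Gibbs ----
        for i in range(n_fixed):
            diag = 0.0
            s = 0.0
            for t in range(indptr[i], indptr[i + 1]):
                j = indices[t]
                if j == i:
                    diag = dataU[t]
                else:
                    s += dataU[t] * theta[j]
            if diag > 0.0:
                mean = (rhs[i] - s) / diag
                theta[i] = mean + np.random.normal() / np.sqrt(diag)
        # ---- animal blocks (additive coefficients, then permanent env.) ----
        for blk in range(n_ped + n_rec):
            b0 = a_off + 6 * blk
            for r in range(6):
                for c in range(6):
                    Cblk[r, c] = 0.0
                i = b0 + r
                s = 0.0
                for t in range(indptr[i], indptr[i + 1]):
                    j = indices[t]
                    if b0 <= j < b0 + 6:
                        Cblk[r, j - b0] = dataU[t]
                    else:
                        s += dataU[t] * theta[j]
                bvec[r] = rhs[i] - s
            if not _chol(Cblk, Lblk):
                tr = 0.0
                for r in range(6):
                    tr += Cblk[r, r]
                for r in range(6):
                    Cblk[r, r] += 1e-8 * tr + 1e-12
                _chol(Cblk, Lblk)
            _chol_solve(Lblk, bvec, mvec)
            for r in range(6):
                zvec[r] = np.random.normal()
            for r in range(5, -1, -1):
                s = zvec[r]
                for k in range(r + 1, 6):
                    s -= Lblk[k, r] * xvec[k]
                xvec[r] = s / Lblk[r, r]
            for r in range(6):
                theta[b0 + r] = mvec[r] + xvec[r]
        # ---- additive/PE split swap (likelihood-invariant Gibbs move) ----
        # A recorded animal's additive and PE 6-vectors enter the records
        # only through their sum; resample the split from the prior
        # conditional (additive coupled to relatives through K^-1).
        if rec_ped.shape[0] == n_rec and n_rec > 0:
            for rr in range(n_rec):
                i = rec_ped[rr]
                ai = a_off + 6 * i
                pi = p_off + 6 * rr
                kii = 0.0
                for r in range(6):
                    svec6[r] = theta[ai + r] + theta[pi + r]
                    vvec6[r] = 0.0
                for t in range(k_indptr[i], k_indptr[i + 1]):
                    j = k_indices[t]
                    if j == i:
                        kii = k_data[t]
                    else:
                        aj = a_off + 6 * j
                        w = k_data[t]
                        for r in range(6):
                            vvec6[r] -= w * theta[aj + r]
                for r in range(6):
                    b6 = 0.0
                    for cidx in range(6):
                        b6 += G0inv[r, cidx] * vvec6[cidx]
                        b6 += P0inv[r, cidx] * svec6[cidx]
                        Cblk[r, cidx] = kii * G0inv[r, cidx] + P0inv[r, cidx]
                    bvec[r] = b6
                if not _chol(Cblk, Lblk):
                    tr = 0.0
                    for r in range(6):
                        tr += Cblk[r, r]
                    for r in range(6):
                        Cblk[r, r] += 1e-8 * tr + 1e-12
                    _chol(Cblk, Lblk)
                _chol_solve(Lblk, bvec, mvec)
                for r in range(6):
                    zvec[r] = np.random.normal()
                for r in range(5, -1, -1):
                    s = zvec[r]
                    for k in range(r + 1, 6):
                        s -= Lblk[k, r] * xvec[k]
                    xvec[r] = s / Lblk[r, r]
                for r in range(6):
                    anew = mvec[r] + xvec[r]
                    theta[ai + r] = anew
                    theta[pi + r] = svec6[r] - anew
        # ---- intercept-split swap (likelihood-invariant Gibbs move) ----
        # The DIM and THI trajectory intercepts enter every record only
        # through their sum, so given the sums the split follows the prior
        # conditional: precision c K^-1 with local means -r/c (Lk = chol K).
        if Lk.shape[0] == n_ped:
            c = G0inv[0, 0] + G0inv[4, 4] - 2.0 * G0inv[0, 4]
            if c > 0.0:
                for i in range(n_ped):
                    b0 = a_off + 6 * i
                    s_i = theta[b0] + theta[b0 + 4]
                    r = (G0inv[0, 4] - G0inv[4, 4]) * s_i
                    for k in (1, 2, 3, 5):
                        r += (G0inv[0, k] - G0inv[4, k]) * theta[b0 + k]
                    swap_mu[i] = -r / c
                    swap_s[i] = s_i
                    swap_z[i] = np.random.normal()
                inv_sqrt_c = 1.0 / np.sqrt(c)
                for i in range(n_ped):
                    acc = 0.0
                    for j in range(i + 1):
                        acc += Lk[i, j] * swap_z[j]
                    u = swap_mu[i] + inv_sqrt_c * acc
                    theta[a_off + 6 * i] = u
                    theta[a_off + 6 * i + 4] = swap_s[i] - u
            # permanent-environment intercepts: i.i.d. prior, same move
            cp = P0inv[0, 0] + P0inv[4, 4] - 2.0 * P0inv[0, 4]
            if cp > 0.0:
                inv_sqrt_cp = 1.0 / np.sqrt(cp)
                for i in range(n_rec):
                    b0 = p_off + 6 * i
                    s_i = theta[b0] + theta[b0 + 4]
                    r = (P0inv[0, 4] - P0inv[4, 4]) * s_i
                    for k in (1, 2, 3, 5):
                        r += (P0inv[0, k] - P0inv[4, k]) * theta[b0 + k]
                    u = -r / cp + inv_sqrt_cp * np.random.normal()
                    theta[b0] = u
                    theta[b0 + 4] = s_i - u
        # ---- residual variances ----
        for o in range(6):
            sse[o] = 0.0
        for m in range(y.shape[0]):
            pred = 0.0
            for t in range(w_indptr[m], w_indptr[m + 1]):
                pred += w_data[t] * theta[w_indices[t]]
            e = y[m] - pred
            sse[rclass[m]] += e * e
        for o in range(6):
            sig[o] = (sse[o] + nu_e * se0[o]) / np.random.chisquare(
                nclass[o] + nu_e
            )
        # ---- additive covariance matrix ----
        for r in range(6):
            for c in range(6):
                Sa[r, c] = 0.0
        for k in range(ainv_val.shape[0]):
            v = ainv_val[k]
            ia = a_off + 6 * ainv_i[k]
            ja = a_off + 6 * ainv_j[k]
            for r in range(6):
                tr_ = v * theta[ia + r]
                for c in range(6):
                    Sa[r, c] += tr_ * theta[ja + c]
        for r in range(6):
            for c in range(6):
                Sscale[r, c] = Sa[r, c] + Sa0[r, c]
        _inv_wishart(nu_a + n_ped, Sscale, G0)
        # ---- permanent-environment covariance matrix ----
        for r in range(6):
            for c in range(6):
                Sp[r, c] = 0.0
        for a in range(n_rec):
            i0 = p_off + 6 * a
            for r in range(6):
                tr_ = theta[i0 + r]
                for c in range(6):
                    Sp[r, c] += tr_ * theta[i0 + c]
        for r in range(6):
            for c in range(6):
                Sscale[r, c] = Sp[r, c] + Sp0[r, c]
        _inv_wishart(nu_p + n_rec, Sscale, P0)
        # ---- retain ----
        if it > burnin and (it - burnin) % thin == 0:
            for r in range(6):
                for c in range(6):
                    out_G[kept, r, c] = G0[r, c]
                    out_P[kept, r, c] = P0[r, c]
                out_s[kept, r] = sig[r]
            for i in range(ncoef):
                theta_mean[i] += theta[i]
            kept += 1
    if kept > 0:
        for i in range(ncoef):
            theta_mean[i] /= kept
    return kept
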