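"""Multivariate-normal likelihood kernels for variance-component models.

Two evaluation paths share one interface:

- dense: one Cholesky factorization of the full n x n covariance per
  evaluation (O(n^3)); required when relationship matrices have nonzero
  entries between families (e.g. a raw IBS GRM);
- blocked: when every covariance term is block-diagonal with respect to
  the family partition, the likelihood factorizes over families and is
  evaluated with batched small-matrix linear algebra (O(n) for twin-pair
  data), which is orders of magnitude faster.

Both paths return the negative log-likelihood and its analytic gradient.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

LOG2PI = float(np.log(2.0 * np.pi))


class FamilyBlocks:
    """Partition of samples into families, grouped by family size for batching."""

    def __init__(self, family_labels):
        family_labels = np.asarray(family_labels)
        self.n = family_labels.size
        # preserve first-appearance order of families
        _, first = np.unique(family_labels, return_index=True)
        fams = family_labels[np.sort(first)]
        idx_by_fam = {f: np.where(family_labels == f)[0] for f in fams}
        by_size: dict[int, list[np.ndarray]] = {}
        for f in fams:
            by_size.setdefault(idx_by_fam[f].size, []).append(idx_by_fam[f])
        # (size -> (F, size) index array)
        self.groups = {s: np.vstack(lst) for s, lst in by_size.items()}

    def gather_vec(self, v):
        v = np.asarray(v)
        return {s: v[g] for s, g in self.groups.items()}

    def gather_mat(self, M):
        out = {}
        for s, g in self.groups.items():
            out[s] = M[g[:, :, None], g[:, None, :]]
        return out

    def is_block_diagonal(self, M, tol: float = 0.0) -> bool:
        total = float(np.abs(M).sum())
        inside = sum(float(np.abs(b).sum()) for b in self.gather_mat(M).values())
        return abs(total - inside) <= tol * max(total, 1.0) + 1e-12


# ---------------------------------------------------------------------------
# linear variance components: V = sum_k w_k * K_k
# ---------------------------------------------------------------------------


def dense_nll_grad_linear(y, mu, weights, mats):
    """NLL and gradient for V = sum_k weights[k] * mats[k].

    Returns (nll, grad_weights, grad_mu). Gradient of the NLL w.r.t. w_k is
    0.5 * (tr(V^-1 K_k) - r' V^-1 K_k V^-1 r) and w.r.t. mu is -1' V^-1 r.
    """
    n = y.size
    V = np.zeros((n, n))
    for w, K in zip(weights, mats):
        V += w * K
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, np.full(len(weights), np.nan), np.nan
    logdet = 2.0 * np.log(np.diag(c)).sum()
    r = y - mu
    u = linalg.cho_solve((c, low), r, check_finite=False)
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    nll = 0.5 * (logdet + r @ u + n * LOG2PI)
    grad_w = np.array(
        [0.5 * ((Vinv * K).sum() - u @ K @ u) for K in mats]
    )
    grad_mu = -float(u.sum())
    return nll, grad_w, grad_mu


def blocked_nll_grad_linear(y, mu, weights, block_mats, blocks: FamilyBlocks):
    """Blocked counterpart of :func:`dense_nll_grad_linear`.

    ``block_mats`` is a list (one per variance term) of dicts mapping family
    size -> (F, s, s) stacked blocks, as produced by ``blocks.gather_mat``.
    """
    r_parts = blocks.gather_vec(y)
    nll = 0.0
    grad_w = np.zeros(len(weights))
    grad_mu = 0.0
    n = 0
    for s, g in blocks.groups.items():
        F = g.shape[0]
        V = np.zeros((F, s, s))
        for w, Kd in zip(weights, block_mats):
            V += w * Kd[s]
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, np.full(len(weights), np.nan), np.nan
        logdet = 2.0 * np.log(np.diagonal(c, axis1=1, axis2=2)).sum()
        r = r_parts[s] - mu
        u = np.linalg.solve(V, r[..., None])[..., 0]
        Vinv = np.linalg.inv(V)
        nll += 0.5 * (logdet + np.einsum("fi,fi->", r, u) + F * s * LOG2PI)
        for k, Kd in enumerate(block_mats):
            K = Kd[s]
            tr = np.einsum("fij,fij->", Vinv, K)
            quad = np.einsum("fi,fij,fj->", u, K, u)
            grad_w[k] += 0.5 * (tr - quad)
        grad_mu += -float(u.sum())
        n += F * s
    return nll, grad_w, grad_mu


# ---------------------------------------------------------------------------
# moderated covariance: V = (sg sg') o A + diag(se^2)
# ---------------------------------------------------------------------------


def dense_nll_grad_moderation(y, mu, sg, se, m, A):
    """NLL and gradient for V_ij = A_ij sg_i sg_j + delta_ij se_i^2.

    ``sg = sigma_a + beta_g * m`` and ``se = sigma_e + beta_e * m``; the
    gradient is returned w.r.t. (sigma_a, beta_g, sigma_e, beta_e, mu).
    """
    n = y.size
    V = A * np.outer(sg, sg)
    V[np.diag_indices(n)] += se**2
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, np.full(5, np.nan)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    r = y - mu
    u = linalg.cho_solve((c, low), r, check_finite=False)
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    nll = 0.5 * (logdet + r @ u + n * LOG2PI)

    W = Vinv * A  # elementwise
    Au_usg = A @ (u * sg)
    grad = np.empty(5)
    for k, d in ((0, np.ones(n)), (1, m)):
        # dV = A o (d sg' + sg d')
        tr = 2.0 * d @ (W @ sg)
        quad = 2.0 * (u * d) @ Au_usg
        grad[k] = 0.5 * (tr - quad)
    diag_vinv = np.diag(Vinv)
    for k, d in ((2, np.ones(n)), (3, m)):
        dv = 2.0 * se * d  # diagonal of dV
        tr = diag_vinv @ dv
        quad = (u**2) @ dv
        grad[k] = 0.5 * (tr - quad)
    grad[4] = -float(u.sum())
    return nll, grad


def blocked_nll_grad_moderation(y, mu, sg, se, m, A_blocks, blocks: FamilyBlocks):
    """Blocked counterpart of :func:`dense_nll_grad_moderation`."""
    r_parts = blocks.gather_vec(y)
    sg_parts = blocks.gather_vec(sg)
    se_parts = blocks.gather_vec(se)
    m_parts = blocks.gather_vec(m)
    nll = 0.0
    grad = np.zeros(5)
    for s, g in blocks.groups.items():
        F = g.shape[0]
        A = A_blocks[s]
        sgb, seb, mb = sg_parts[s], se_parts[s], m_parts[s]
        V = A * (sgb[:, :, None] * sgb[:, None, :])
        V[:, np.arange(s), np.arange(s)] += seb**2
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, np.full(5, np.nan)
        logdet = 2.0 * np.log(np.diagonal(c, axis1=1, axis2=2)).sum()
        r = r_parts[s] - mu
        u = np.linalg.solve(V, r[..., None])[..., 0]
        Vinv = np.linalg.inv(V)
        nll += 0.5 * (logdet + np.einsum("fi,fi->", r, u) + F * s * LOG2PI)

        W = Vinv * A
        Au_usg = np.einsum("fij,fj->fi", A, u * sgb)
        ones = np.ones_like(mb)
        for k, d in ((0, ones), (1, mb)):
            tr = 2.0 * np.einsum("fi,fij,fj->", d, W, sgb)
            quad = 2.0 * np.einsum("fi,fi->", u * d, Au_usg)
            grad[k] += 0.5 * (tr - quad)
        diag_vinv = np.diagonal(Vinv, axis1=1, axis2=2)
        for k, d in ((2, ones), (3, mb)):
            dv = 2.0 * seb * d
            tr = np.einsum("fi,fi->", diag_vinv, dv)
            quad = np.einsum("fi,fi->", u**2, dv)
            grad[k] += 0.5 * (tr - quad)
        grad[4] += -float(u.sum())
    return nll, grad


def numerical_hessian(f, x, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar function ``f`` at ``x``."""
    x = np.asarray(x, float)
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return H
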