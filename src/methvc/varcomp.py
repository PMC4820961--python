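"""Two-GRM mixed model: SNP-tagged vs total genetic variance per site.

For standardized methylation residuals y the covariance between
individuals is modelled as

    V = sigma2_snp * A_IBS + sigma2_ped * A_IBD + sigma2_e * I

where A_IBS is the genome-wide SNP relationship matrix and A_IBD its
thresholded variant in which distant relationships are zeroed.  Because
close relatives appear (nearly) identically in both matrices, sigma2_snp
captures variance tagged by the genotyped SNPs (identified through the
faint relatedness between nominally unrelated individuals) while
sigma2_ped absorbs the remaining, untagged additive genetic variance;
their sum is the total additive genetic variance.  Derived quantities:

    h2_IBD  = (sigma2_snp + sigma2_ped) / (sigma2_snp + sigma2_ped + sigma2_e)
    h2_SNPs =  sigma2_snp               / (sigma2_snp + sigma2_ped + sigma2_e)

and the share of heritability tagged by SNPs, h2_SNPs / h2_IBD.

Variances are optimized on the log scale (maximum likelihood with a free
intercept); non-negativity of sigma2_ped enforces h2_SNPs <= h2_IBD by
construction.  Standard errors come from the observed information
(numerical Hessian on the variance scale); components pinned at ~0 are
flagged as boundary solutions with undefined SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._gaussian import (
    FamilyBlocks,
    blocked_nll_grad_linear,
    dense_nll_grad_linear,
    numerical_hessian,
)
from .kinship import Grm

__all__ = ["TwoGrmFit", "fit_two_grm", "heritability_ratios", "twin_grm_equivalence_check"]

_BOUNDARY_VAR = 1e-8
_LOG_LO, _LOG_HI = np.log(1e-10), np.log(1e3)


@dataclass
class TwoGrmFit:
    sigma2_snp: float
    sigma2_ped: float
    sigma2_e: float
    h2_ibd: float
    h2_snps: float
    ratio_snp: float
    se_sigma2_snp: float
    se_sigma2_ped: float
    se_sigma2_e: float
    loglik: float
    mean: float
    converged: bool
    boundary: dict = field(default_factory=dict)
    status: str = "ok"


def _check_psd(A: np.ndarray, name: str) -> None:
    n = A.shape[0]
    ev_min = float(np.linalg.eigvalsh(A)[0])
    if ev_min < -1e-6 * np.trace(A) / n:
        raise ValueError(f"{name} is indefinite beyond tolerance (min eigenvalue {ev_min:.3g})")


def fit_two_grm(
    y,
    grm_ibs: Grm,
    grm_ibd: Grm,
    families=None,
    fix_snp_zero: bool = False,
    compute_se: bool = True,
    check_psd: bool = False,
    n_restarts: int = 2,
    seed: int = 0,
    h2_floor: float = 1e-6,
) -> TwoGrmFit:
    """ML fit of the two-GRM model for one site.

    ``families`` (optional per-sample labels) enables the fast blocked
    likelihood when every covariance term is block-diagonal over families
    (e.g. with a pedigree-expected GRM); otherwise the dense path is used.
    ``fix_snp_zero`` constrains sigma2_snp to 0, reducing the model to a
    single-GRM (AE-equivalent) fit.
    """
    y = np.asarray(y, float)
    n = y.size
    A1, A2 = grm_ibs.matrix, grm_ibd.matrix
    if A1.shape[0] != n or A2.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: y has {n} samples, GRMs have "
            f"{A1.shape[0]} and {A2.shape[0]}"
        )
    if list(grm_ibs.sample_ids) != list(grm_ibd.sample_ids):
        raise ValueError("GRM sample ids differ between the two matrices")
    if check_psd:
        _check_psd(A1, "IBS GRM")
        _check_psd(A2, "IBD GRM")

    identity = np.eye(n)
    mats = ([A2, identity] if fix_snp_zero else [A1, A2, identity])
    n_var = len(mats)

    blocks = None
    if families is not None:
        fb = FamilyBlocks(families)
        if all(fb.is_block_diagonal(M) for M in mats[:-1]):
            blocks = fb
            block_mats = [fb.gather_mat(M) for M in mats]

    def nll_grad(params):
        mu = params[-1]
        w = np.exp(params[:-1])
        if blocks is not None:
            nll, gw, gmu = blocked_nll_grad_linear(y, mu, w, block_mats, blocks)
        else:
            nll, gw, gmu = dense_nll_grad_linear(y, mu, w, mats)
        if not np.isfinite(nll):
            return np.inf, np.zeros(n_var + 1)
        return nll, np.concatenate([gw * w, [gmu]])

    var_y = y.var(ddof=0)
    rng = np.random.default_rng(seed)
    starts = [np.concatenate([np.log(np.full(n_var, max(var_y, 1e-3) / n_var)), [y.mean()]])]
    for _ in range(n_restarts - 1):
        w0 = var_y * rng.dirichlet(np.ones(n_var)) + 1e-4
        starts.append(np.concatenate([np.log(w0), [y.mean() + rng.normal(0, 0.1)]]))

    best, converged = None, False
    bounds = [(_LOG_LO, _LOG_HI)] * n_var + [(None, None)]
    for x0 in starts:
        res = optimize.minimize(
            nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    w_hat = np.exp(best.x[:-1])
    mu_hat = float(best.x[-1])
    if fix_snp_zero:
        s_snp, (s_ped, s_e) = 0.0, w_hat
    else:
        s_snp, s_ped, s_e = w_hat

    # identical matrices make the snp/ped split a ridge in the likelihood
    split_unidentifiable = (not fix_snp_zero) and np.abs(A1 - A2).max() < 1e-8
    boundary = {
        "sigma2_snp": bool(
            (not fix_snp_zero and s_snp < _BOUNDARY_VAR) or split_unidentifiable
        ),
        "sigma2_ped": bool(s_ped < _BOUNDARY_VAR or split_unidentifiable),
        "sigma2_e": bool(s_e < _BOUNDARY_VAR),
    }
    s_snp = 0.0 if s_snp < _BOUNDARY_VAR else s_snp
    s_ped = 0.0 if s_ped < _BOUNDARY_VAR else s_ped

    total = s_snp + s_ped + s_e
    h2_ibd = (s_snp + s_ped) / total if total > 0 else np.nan
    h2_snps = s_snp / total if total > 0 else np.nan

    ses = [np.nan] * 3
    if compute_se:
        free = [k for k, w in enumerate(w_hat) if w >= _BOUNDARY_VAR]
        if free:
            def nll_var_scale(v):
                w = w_hat.copy()
                w[free] = v
                if blocks is not None:
                    out = blocked_nll_grad_linear(y, mu_hat, w, block_mats, blocks)[0]
                else:
                    out = dense_nll_grad_linear(y, mu_hat, w, mats)[0]
                return out

            step = max(1e-5, 1e-3 * float(w_hat[free].min()))
            H = numerical_hessian(nll_var_scale, w_hat[free], step=step)
            try:
                cov = np.linalg.inv(H)
                dse = np.sqrt(np.maximum(np.diag(cov), 0.0))
                for pos, k in enumerate(free):
                    ses_k = k if not fix_snp_zero else k + 1
                    ses[ses_k] = float(dse[pos])
            except np.linalg.LinAlgError:
                pass

    fit = TwoGrmFit(
        sigma2_snp=float(s_snp),
        sigma2_ped=float(s_ped),
        sigma2_e=float(s_e),
        h2_ibd=float(h2_ibd),
        h2_snps=float(h2_snps),
        ratio_snp=np.nan,
        se_sigma2_snp=ses[0],
        se_sigma2_ped=ses[1],
        se_sigma2_e=ses[2],
        loglik=-float(best.fun),
        mean=mu_hat,
        converged=converged,
        boundary=boundary,
        status="ok" if converged else "non_converged",
    )
    fit.ratio_snp = heritability_ratios(fit, h2_floor=h2_floor)
    return fit


def heritability_ratios(fit: TwoGrmFit | tuple, h2_floor: float = 1e-6) -> float:
    """Share of the heritability tagged by SNPs: h2_SNPs / h2_IBD.

    Undefined (NaN) when h2_IBD is below ``h2_floor``; such sites are
    excluded from catalogue summaries of the ratio.
    """
    if isinstance(fit, tuple):
        h2_snps, h2_ibd = fit
    else:
        h2_snps, h2_ibd = fit.h2_snps, fit.h2_ibd
    if not np.isfinite(h2_ibd) or h2_ibd < h2_floor:
        return float("nan")
    return float(h2_snps / h2_ibd)


def twin_grm_equivalence_check(
    site_values: np.ndarray,
    ped,
    grm_ped: Grm,
    sample_ids=None,
    seed: int = 0,
) -> dict:
    """Compare twin AE heritability against the pedigree-GRM mixed model.

    For each site (rows of ``site_values``) fits (a) the classical AE twin
    model on complete twin pairs and (b) the mixed model with the
    pedigree-expected relatedness matrix and sigma2_snp fixed at 0, then
    reports the correlation and mean absolute difference of the two
    heritability estimates.  The two estimators target the same quantity,
    so on twin data they should agree closely.
    """
    from .twin import fit_twin_model, twin_pairs_from_pedigree

    site_values = np.atleast_2d(np.asarray(site_values, float))
    ids = list(sample_ids) if sample_ids is not None else list(ped["sample_id"])
    if list(grm_ped.sample_ids) != ids:
        raise ValueError("sample ids of the GRM do not match the value matrix")
    fams = ped.set_index("sample_id").loc[ids, "family_id"].to_numpy()

    h2_twin, h2_grm = [], []
    for k, row in enumerate(site_values):
        pairs = twin_pairs_from_pedigree(row, ped, sample_ids=ids)
        ae = fit_twin_model(pairs, "AE", seed=seed + k)
        fit = fit_two_grm(
            row, grm_ped, grm_ped, families=fams, fix_snp_zero=True,
            compute_se=False, seed=seed + k,
        )
        h2_twin.append(ae.a2)
        h2_grm.append(fit.h2_ibd)
    h2_twin = np.array(h2_twin)
    h2_grm = np.array(h2_grm)
    out = {
        "h2_twins": h2_twin,
        "h2_ibd": h2_grm,
        "mean_abs_diff": float(np.mean(np.abs(h2_twin - h2_grm))),
    }
    if len(h2_twin) >= 3 and h2_twin.std() > 0 and h2_grm.std() > 0:
        out["correlation"] = float(np.corrcoef(h2_twin, h2_grm)[0, 1])
    else:
        out["correlation"] = float("nan")
    return out
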