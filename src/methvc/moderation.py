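"""Genome-by-age and genome-by-sex variance-moderation models.

The moderation model lets the additive-genetic and unique-environment
standard deviations vary linearly in a moderator m (sex coded 0/1, or age
z-transformed):

    V_ij = A_ij (sigma_a + beta_g m_i)(sigma_a + beta_g m_j)
           + delta_ij (sigma_e + beta_e m_i)^2

so beta_g measures the interaction of genetic effects with the moderator
and beta_e the interaction of residual effects with it.  A single total
genetic component with the close-relative (IBD-thresholded or
pedigree-expected) relationship matrix is used; the interaction questions
concern total genetic vs environmental variance, not the SNP-tagged split.

Interaction significance is a 1-df Wald chi-square, chi2 = (beta / s.e.)^2,
with standard errors from the observed information (central-difference
Hessian).  The joint sign indeterminacy of (sigma_a, beta_g) — the
likelihood is invariant under flipping both — is resolved by reporting
sigma_a >= 0 (likewise sigma_e).

Heritability trajectories follow directly:

    Va(m) = (sigma_a + beta_g m)^2,  Ve(m) = (sigma_e + beta_e m)^2,
    h2(m) = Va(m) / (Va(m) + Ve(m)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._gaussian import (
    FamilyBlocks,
    blocked_nll_grad_moderation,
    dense_nll_grad_moderation,
    numerical_hessian,
)
from .kinship import Grm

__all__ = [
    "Moderator",
    "ModerationFit",
    "moderator_from_age",
    "moderator_from_sex",
    "fit_moderation",
    "wald_chi2",
    "h2_at",
    "variance_profile",
    "multiple_testing_threshold",
]


@dataclass
class Moderator:
    values: np.ndarray
    kind: str  # "sex01" | "age_z"
    source_mean: float | None = None
    source_sd: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.kind == "sex01":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("sex moderator must be coded 0/1")
        elif self.kind != "age_z":
            raise ValueError(f"unknown moderator kind {self.kind!r}")


def moderator_from_age(ages, mean: float | None = None, sd: float | None = None) -> Moderator:
    """z-transform ages; by default using the analysis sample's own mean/sd.

    The source mean and s.d. are stored so that heritability at specific
    ages (e.g. 25 and 50 years) can be evaluated on the fitted scale.
    """
    ages = np.asarray(ages, float)
    if mean is None:
        mean = float(ages.mean())
    if sd is None:
        sd = float(ages.std(ddof=0))
    if sd <= 0:
        raise ValueError("age standard deviation must be positive")
    return Moderator(values=(ages - mean) / sd, kind="age_z", source_mean=mean, source_sd=sd)


def moderator_from_sex(sexes) -> Moderator:
    return Moderator(values=np.asarray(sexes, float), kind="sex01")


@dataclass
class ModerationFit:
    sigma_a: float
    beta_g: float
    sigma_e: float
    beta_e: float
    se_beta_g: float
    se_beta_e: float
    chi2_g: float
    chi2_e: float
    p_g: float
    p_e: float
    loglik: float
    mean: float
    converged: bool
    moderator_kind: str = ""
    source_mean: float | None = None
    source_sd: float | None = None


def fit_moderation(
    y,
    grm: Grm,
    moderator: Moderator,
    families=None,
    n_restarts: int = 3,
    seed: int = 0,
    compute_se: bool = True,
) -> ModerationFit:
    """ML fit of the variance-moderation model for one site.

    ``families`` enables the fast family-blocked likelihood when the
    relationship matrix is block-diagonal over families.
    """
    y = np.asarray(y, float)
    n = y.size
    A = grm.matrix
    if A.shape[0] != n:
        raise ValueError(f"dimension mismatch: y has {n} samples, GRM has {A.shape[0]}")
    m = moderator.values
    if m.size != n:
        raise ValueError("moderator length does not match y")
    if np.ptp(m) == 0:
        raise ValueError("constant moderator: interaction coefficients unidentifiable")

    blocks = None
    if families is not None:
        fb = FamilyBlocks(families)
        if fb.is_block_diagonal(A):
            blocks = fb
            A_blocks = fb.gather_mat(A)

    def nll_grad(params):
        sigma_a, beta_g, sigma_e, beta_e, mu = params
        sg = sigma_a + beta_g * m
        se = sigma_e + beta_e * m
        if blocks is not None:
            nll, grad = blocked_nll_grad_moderation(y, mu, sg, se, m, A_blocks, blocks)
        else:
            nll, grad = dense_nll_grad_moderation(y, mu, sg, se, m, A)
        if not np.isfinite(nll):
            return np.inf, np.zeros(5)
        return nll, grad

    sd_y = y.std(ddof=0)
    if sd_y <= 0:
        raise ValueError("zero variance in y")
    rng = np.random.default_rng(seed)
    starts = [np.array([0.45 * sd_y, 0.0, 0.85 * sd_y, 0.0, y.mean()])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.array(
                [
                    sd_y * rng.uniform(0.1, 0.9),
                    rng.normal(0, 0.1),
                    sd_y * rng.uniform(0.3, 1.0),
                    rng.normal(0, 0.1),
                    y.mean() + rng.normal(0, 0.1),
                ]
            )
        )

    best, converged = None, False
    for x0 in starts:
        res = optimize.minimize(
            nll_grad, x0, jac=True, method="L-BFGS-B", options={"maxiter": 500}
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    sigma_a, beta_g, sigma_e, beta_e, mu = best.x
    # resolve sign indeterminacies: likelihood invariant under joint flips
    if sigma_a < 0:
        sigma_a, beta_g = -sigma_a, -beta_g
    if sigma_e < 0:
        sigma_e, beta_e = -sigma_e, -beta_e

    se_bg = se_be = np.nan
    if compute_se:
        x_hat = np.array([sigma_a, beta_g, sigma_e, beta_e, mu])

        def nll_only(x):
            return nll_grad(x)[0]

        H = numerical_hessian(nll_only, x_hat, step=1e-4)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.all(np.isfinite(d)) and d[1] > 0 and d[3] > 0:
                se_bg = float(np.sqrt(d[1]))
                se_be = float(np.sqrt(d[3]))
        except np.linalg.LinAlgError:
            pass

    chi2_g, p_g = (wald_chi2(beta_g, se_bg) if np.isfinite(se_bg) else (np.nan, np.nan))
    chi2_e, p_e = (wald_chi2(beta_e, se_be) if np.isfinite(se_be) else (np.nan, np.nan))

    return ModerationFit(
        sigma_a=float(sigma_a),
        beta_g=float(beta_g),
        sigma_e=float(sigma_e),
        beta_e=float(beta_e),
        se_beta_g=se_bg,
        se_beta_e=se_be,
        chi2_g=chi2_g,
        chi2_e=chi2_e,
        p_g=p_g,
        p_e=p_e,
        loglik=-float(best.fun),
        mean=float(mu),
        converged=converged,
        moderator_kind=moderator.kind,
        source_mean=moderator.source_mean,
        source_sd=moderator.source_sd,
    )


def wald_chi2(beta: float, se: float):
    """1-df Wald test: chi2 = (beta/se)^2, p = upper chi-square tail."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    stat = (beta / se) ** 2
    return float(stat), float(stats.chi2.sf(stat, 1))


def h2_at(fit: ModerationFit, m_value: float) -> float:
    """Heritability at a moderator value; NaN when total variance is 0 there."""
    va = (fit.sigma_a + fit.beta_g * m_value) ** 2
    ve = (fit.sigma_e + fit.beta_e * m_value) ** 2
    tot = va + ve
    if tot == 0:
        return float("nan")
    return float(va / tot)


def variance_profile(fit: ModerationFit, m_grid) -> dict[str, np.ndarray]:
    """Va(m), Ve(m), total variance and h2(m) along a moderator grid."""
    m_grid = np.asarray(m_grid, float)
    va = (fit.sigma_a + fit.beta_g * m_grid) ** 2
    ve = (fit.sigma_e + fit.beta_e * m_grid) ** 2
    tot = va + ve
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(tot > 0, va / tot, np.nan)
    return {"m": m_grid, "va": va, "ve": ve, "vtot": tot, "h2": h2}


def age_to_moderator_value(fit: ModerationFit, age_years: float) -> float:
    """Convert an age in years to the fitted z scale."""
    if fit.source_mean is None or fit.source_sd is None:
        raise ValueError("fit does not carry an age scale")
    return (age_years - fit.source_mean) / fit.source_sd


def multiple_testing_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
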