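"""Methylation value transforms, probe/sample QC and covariate correction.

Implements the standard Illumina-450k-style preprocessing contract:

- beta values from methylated/unmethylated intensities with offset
  ``alpha`` (default 100): ``beta = M / (M + U + alpha)``,
- the M value as the log2-logistic transform ``M = log2(beta/(1-beta))``,
- probe filters (per-cell detection P > 0.01, bead count < 3, zero
  intensity; probe success rate < 0.95 across samples; blacklists for
  ambiguously mapped probes and probes with a SNP at the CpG),
- sample contamination calling from 65 SNP control probes,
- missing-value imputation, per-site covariate residualization and
  z-standardization, and family-cluster-robust covariate association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethylationMatrix",
    "ProbeQcInputs",
    "QcReport",
    "beta_from_intensities",
    "m_from_beta",
    "beta_from_m",
    "apply_probe_filters",
    "count_unclear_genotypes",
    "impute_missing",
    "build_design",
    "residualize",
    "zstandardize",
    "site_covariate_association",
]

BETA_EPS = 1e-6  # clamp for beta -> M at the endpoints


@dataclass
class MethylationMatrix:
    """Sites x samples methylation values with a scale tag.

    ``values`` is a DataFrame indexed by site id with sample-id columns;
    missing cells are NaN. ``scale`` is ``"beta"`` (values in [0, 1]) or
    ``"m"`` (real line) or ``"residual"`` / ``"z"`` after processing.
    """

    values: pd.DataFrame
    scale: str = "m"
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicated site ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        if self.scale == "beta":
            v = self.values.to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                    raise ValueError("beta-scale values must lie in [0, 1]")

    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def read_tsv(cls, path, scale: str = "m") -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(values=df, scale=scale)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class ProbeQcInputs:
    """Per-cell QC matrices and probe blacklists, aligned to the methylation matrix."""

    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None
    intensity_zero: pd.DataFrame | None = None
    blacklist_ambiguous: frozenset = frozenset()
    blacklist_snp_at_cpg: frozenset = frozenset()


@dataclass
class QcReport:
    n_sites_in: int
    n_sites_out: int
    removed_blacklist: int
    removed_success_rate: int
    cells_masked_detection_p: int
    cells_masked_bead_count: int
    cells_masked_zero_intensity: int
    sample_success_rate: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_sites_in",
                "n_sites_out",
                "removed_blacklist",
                "removed_success_rate",
                "cells_masked_detection_p",
                "cells_masked_bead_count",
                "cells_masked_zero_intensity",
            )
        }
        if self.sample_success_rate is not None:
            d["mean_sample_success_rate"] = float(self.sample_success_rate.mean())
        return d


# ---------------------------------------------------------------------------
# value transforms
# ---------------------------------------------------------------------------


def beta_from_intensities(M_signal, U_signal, alpha: float = 100.0):
    """Methylation proportion from methylated/unmethylated intensities.

    ``beta = M / (M + U + alpha)``; the offset keeps beta near 0 for probes
    with near-zero overall signal.
    """
    M_signal = np.asarray(M_signal, float)
    U_signal = np.asarray(U_signal, float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if (M_signal < 0).any() or (U_signal < 0).any():
        raise ValueError("intensities must be non-negative")
    out = M_signal / (M_signal + U_signal + alpha)
    return out if out.ndim else float(out)


def m_from_beta(beta, eps: float = BETA_EPS):
    """M value ``log2(beta / (1 - beta))``; beta clamped to [eps, 1-eps]."""
    beta = np.asarray(beta, float)
    if (beta < 0).any() or (beta > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    if ((beta <= 0) | (beta >= 1)).any():
        warnings.warn(
            f"beta values at 0/1 clamped to [{eps}, 1-{eps}] before M transform",
            stacklevel=2,
        )
    b = np.clip(beta, eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def beta_from_m(m):
    """Inverse of :func:`m_from_beta` on the open interval (0, 1)."""
    m = np.asarray(m, float)
    out = 1.0 / (1.0 + np.power(2.0, -m))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# probe filters
# ---------------------------------------------------------------------------


def apply_probe_filters(
    meth: MethylationMatrix,
    qc: ProbeQcInputs,
    detp_max: float = 0.01,
    min_beads: int = 3,
    min_success: float = 0.95,
) -> tuple[MethylationMatrix, QcReport]:
    """Apply probe-level QC.

    Order: (1) blacklisted probes (ambiguous mapping, SNP at the CpG) are
    removed globally; (2) per-cell failures (detection P > ``detp_max``,
    bead count < ``min_beads``, zero intensity) are set missing; (3) probes
    with success rate < ``min_success`` across samples are dropped.  The
    report records removals by reason and per-sample success rates over the
    retained probes.
    """
    if not 0.0 < detp_max < 1.0:
        raise ValueError("detp_max must lie in (0, 1)")
    if not 0.0 < min_success <= 1.0:
        raise ValueError("min_success must lie in (0, 1]")

    values = meth.values.copy()
    n_in = len(values)

    blacklist = (set(qc.blacklist_ambiguous) | set(qc.blacklist_snp_at_cpg)) & set(
        values.index
    )
    values = values.drop(index=sorted(blacklist))

    def _aligned(mat):
        if mat is None:
            return None
        if len(values.index.difference(mat.index)):
            raise ValueError("QC matrix does not cover all probes")
        if len(values.columns.difference(mat.columns)):
            raise ValueError("QC matrix does not cover all samples")
        return mat.loc[values.index, values.columns]

    n_detp = n_beads = n_zero = 0
    detp = _aligned(qc.detection_p)
    if detp is not None:
        bad = detp.to_numpy(float) > detp_max
        n_detp = int(np.nansum(bad & values.notna().to_numpy()))
        values = values.mask(pd.DataFrame(bad, index=values.index, columns=values.columns))
    beads = _aligned(qc.bead_count)
    if beads is not None:
        bad = beads.to_numpy(float) < min_beads
        n_beads = int(np.nansum(bad & values.notna().to_numpy()))
        values = values.mask(pd.DataFrame(bad, index=values.index, columns=values.columns))
    zero = _aligned(qc.intensity_zero)
    if zero is not None:
        bad = zero.to_numpy(bool)
        n_zero = int(np.nansum(bad & values.notna().to_numpy()))
        values = values.mask(pd.DataFrame(bad, index=values.index, columns=values.columns))

    success = values.notna().mean(axis=1)
    keep = success >= min_success
    n_success_removed = int((~keep).sum())
    values = values.loc[keep]

    sample_success = values.notna().mean(axis=0)
    report = QcReport(
        n_sites_in=n_in,
        n_sites_out=len(values),
        removed_blacklist=len(blacklist),
        removed_success_rate=n_success_removed,
        cells_masked_detection_p=n_detp,
        cells_masked_bead_count=n_beads,
        cells_masked_zero_intensity=n_zero,
        sample_success_rate=sample_success,
    )
    return MethylationMatrix(values=values, scale=meth.scale), report


def count_unclear_genotypes(
    proportions, exclude_at: int = 15
) -> tuple[int, bool]:
    """Count 'unclear genotypes' among SNP control-probe allele proportions.

    A proportion is unclear when it lies in [0.2, 0.4] or [0.6, 0.8]
    (closed intervals), i.e. between the three genotype clusters; samples
    with ``count >= exclude_at`` are flagged as potentially contaminated.
    """
    p = np.asarray(proportions, float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("allele-signal proportions must lie in [0, 1]")
    unclear = ((p >= 0.2) & (p <= 0.4)) | ((p >= 0.6) & (p <= 0.8))
    count = int(unclear.sum())
    return count, count >= exclude_at


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_missing(
    meth: MethylationMatrix, method: str = "site_mean", k: int = 10
) -> MethylationMatrix:
    """Fill missing cells; imputed positions are recorded in ``imputed_mask``.

    ``site_mean`` replaces each missing cell by the site's observed mean
    (deterministic default).  ``knn`` replaces it by the mean over the k
    sites most correlated in Euclidean distance over shared samples,
    emulating nearest-neighbour imputation.
    """
    values = meth.values
    mask = values.isna()
    if not mask.to_numpy().any():
        return MethylationMatrix(values=values.copy(), scale=meth.scale, imputed_mask=mask)
    miss_frac = mask.mean(axis=1)
    if (miss_frac >= 0.5).any():
        bad = miss_frac.index[miss_frac >= 0.5][0]
        raise ValueError(f"site {bad} has >=50% missing values; cannot impute")

    if method == "site_mean":
        filled = values.T.fillna(values.mean(axis=1)).T
    elif method == "knn":
        n_sites = len(values)
        if k >= n_sites:
            raise ValueError(f"k={k} must be smaller than the number of sites {n_sites}")
        X = values.to_numpy(float)
        centered = X - np.nanmean(X, axis=1, keepdims=True)
        filled0 = np.where(np.isnan(centered), 0.0, centered)
        # Euclidean distance on mean-centred profiles, missing treated as 0
        d2 = (
            (filled0**2).sum(axis=1)[:, None]
            + (filled0**2).sum(axis=1)[None, :]
            - 2 * filled0 @ filled0.T
        )
        np.fill_diagonal(d2, np.inf)
        filled = X.copy()
        for i in np.where(mask.any(axis=1))[0]:
            nn = np.argsort(d2[i])[:k]
            for j in np.where(mask.iloc[i])[0]:
                donor = X[nn, j]
                donor = donor[~np.isnan(donor)]
                filled[i, j] = donor.mean() if donor.size else np.nanmean(X[i])
        filled = pd.DataFrame(filled, index=values.index, columns=values.columns)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return MethylationMatrix(values=filled, scale=meth.scale, imputed_mask=mask)


# ---------------------------------------------------------------------------
# covariate correction
# ---------------------------------------------------------------------------


def build_design(
    covariates: pd.DataFrame,
    genotype_pcs: pd.DataFrame | None = None,
    include_genotype_pcs: bool = False,
) -> pd.DataFrame:
    """Encode the covariate design matrix (with intercept).

    Continuous columns (age, cell percentages) enter as-is; sex is 0/1;
    array row and plate are dummy coded dropping the first level.  When
    requested, the first ten genotype PCs are appended.
    """
    cov = covariates.set_index("sample_id") if "sample_id" in covariates else covariates
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in ("sex", "age", "neutrophil_pct", "monocyte_pct", "eosinophil_pct"):
        if col in cov:
            parts.append(cov[col].astype(float))
    for col in ("array_row", "plate"):
        if col in cov:
            dummies = pd.get_dummies(cov[col].astype("category"), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    design = pd.concat(parts, axis=1)
    if include_genotype_pcs:
        if genotype_pcs is None:
            raise ValueError("genotype PCs requested but not supplied")
        pcs = genotype_pcs.loc[design.index]
        design = pd.concat([design, pcs.astype(float)], axis=1)
    X = design.to_numpy(float)
    keep = ~np.all(X == X[0], axis=0)
    keep[0] = True  # intercept
    dropped = design.columns[~keep]
    design = design.loc[:, keep]
    if np.linalg.matrix_rank(design.to_numpy(float)) < design.shape[1]:
        # identify collinear columns by incremental rank
        cols, bad = [], []
        mat = np.empty((len(design), 0))
        for c in design.columns:
            cand = np.column_stack([mat, design[c].to_numpy(float)])
            if np.linalg.matrix_rank(cand) > mat.shape[1]:
                mat = cand
                cols.append(c)
            else:
                bad.append(c)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    if len(dropped):
        warnings.warn(f"dropped constant design columns: {list(dropped)}", stacklevel=2)
    return design


def residualize(
    meth: MethylationMatrix, design: pd.DataFrame
) -> tuple[MethylationMatrix, pd.Series]:
    """Per-site OLS residuals against the encoded design; returns (residuals, R2).

    The design must include an intercept column; R2 is the fraction of the
    site's (centred) variance explained by the non-intercept columns.
    """
    values = meth.values
    if values.isna().to_numpy().any():
        raise ValueError("residualize requires a complete matrix; impute first")
    X = design.loc[values.columns].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        cols, bad, mat = [], [], np.empty((n, 0))
        for c in design.columns:
            cand = np.column_stack([mat, design[c].to_numpy(float)])
            if np.linalg.matrix_rank(cand) > mat.shape[1]:
                mat = cand
                cols.append(c)
            else:
                bad.append(c)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    Y = values.to_numpy(float).T  # samples x sites
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    centered = Y - Y.mean(axis=0)
    tss = (centered**2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    out = MethylationMatrix(
        values=pd.DataFrame(resid.T, index=values.index, columns=values.columns),
        scale="residual",
    )
    return out, pd.Series(r2, index=values.index, name="r2")


def zstandardize(meth: MethylationMatrix) -> MethylationMatrix:
    """Per-site z-transform (mean 0, s.d. 1); errors on zero-variance sites."""
    values = meth.values
    if values.isna().to_numpy().any():
        raise ValueError("zstandardize requires a complete matrix")
    sd = values.std(axis=1, ddof=0)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0][0]
        raise ValueError(f"site {bad} has zero variance; cannot standardize")
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return MethylationMatrix(values=z, scale="z")


# ---------------------------------------------------------------------------
# cluster-robust covariate association
# ---------------------------------------------------------------------------


def site_covariate_association(
    meth: MethylationMatrix,
    covariate: pd.Series,
    family_id: pd.Series,
) -> pd.DataFrame:
    """Per-site regression of methylation on one covariate with
    family-cluster-robust (sandwich) standard errors.

    Equivalent to a GEE with independence working correlation and robust
    variance; returns slope, robust s.e., z and two-sided normal p per site.
    """
    values = meth.values
    x = covariate.loc[values.columns].to_numpy(float)
    fam = family_id.loc[values.columns].to_numpy()
    if np.unique(fam).size < 2:
        raise ValueError("need at least two families for cluster-robust errors")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    n = x.size
    X = np.column_stack([np.ones(n), x])
    XtX_inv = np.linalg.inv(X.T @ X)
    Y = values.to_numpy(float).T
    coef = XtX_inv @ X.T @ Y  # 2 x sites
    resid = Y - X @ coef
    # cluster-robust meat: sum over families of (X_f' u_f)(X_f' u_f)'
    codes, _ = pd.factorize(fam)
    n_fam = codes.max() + 1
    slopes = coef[1]
    se = np.empty_like(slopes)
    Xu0 = np.zeros((n_fam, Y.shape[1]))
    Xu1 = np.zeros((n_fam, Y.shape[1]))
    np.add.at(Xu0, codes, resid * X[:, [0]])
    np.add.at(Xu1, codes, resid * X[:, [1]])
    a, b, d = XtX_inv[0, 0], XtX_inv[0, 1], XtX_inv[1, 1]
    # slope row of XtX_inv is (b, d); var(slope) = sum_f (b*Xu0 + d*Xu1)^2
    contrib = b * Xu0 + d * Xu1
    dfc = n_fam / max(n_fam - 1, 1)
    var_slope = dfc * (contrib**2).sum(axis=0)
    se = np.sqrt(var_slope)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = slopes / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"slope": slopes, "se": se, "z": z, "p": p}, index=values.index
    )
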