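"""Classical twin analysis: correlations, Falconer heritability, ACE/ADE ML.

The classical twin design contrasts the resemblance of monozygotic twins
(who share all segregating genetic variants) with dizygotic twins (who
share half additively, a quarter for dominance).  Per methylation site the
package provides

- zygosity-specific Pearson twin correlations (rMZ, rDZ),
- the Falconer moment estimate h2_twins = 2 (rMZ - rDZ),
- maximum-likelihood ACE / ADE / AE / CE / E variance decompositions under
  a bivariate-normal model with a common mean and total variance across
  zygosity groups, with expected covariances

      ACE:  MZ a2 + c2,   DZ a2/2 + c2
      ADE:  MZ a2 + d2,   DZ a2/2 + d2/4

- likelihood-ratio tests between nested models.

Variance components are kept non-negative by a softplus reparameterization
of the component standard deviations; boundary solutions (a component
pinned at ~0) are flagged, and the reported chi-square reference for LRTs
is the conventional (boundary-conservative) one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinPairSet",
    "TwinCorrelations",
    "TwinModelFit",
    "twin_pairs_from_pedigree",
    "twin_correlations",
    "falconer_h2",
    "fit_twin_model",
    "likelihood_ratio_test",
]

MODEL_COMPONENTS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}

_BOUNDARY_VAR = 1e-8


@dataclass
class TwinPairSet:
    """Complete twin pairs: (n_mz, 2) and (n_dz, 2) value arrays."""

    mz: np.ndarray
    dz: np.ndarray

    def __post_init__(self):
        self.mz = np.atleast_2d(np.asarray(self.mz, float))
        self.dz = np.atleast_2d(np.asarray(self.dz, float))
        for name, arr in (("mz", self.mz), ("dz", self.dz)):
            if arr.size and arr.shape[1] != 2:
                raise ValueError(f"{name} pairs must have two columns")
            if np.isnan(arr).any():
                raise ValueError(f"{name} pairs contain missing values; drop incomplete pairs")

    @property
    def n_mz(self) -> int:
        return 0 if self.mz.size == 0 else self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return 0 if self.dz.size == 0 else self.dz.shape[0]


@dataclass
class TwinCorrelations:
    rmz: float
    rdz: float
    n_mz: int
    n_dz: int


@dataclass
class TwinModelFit:
    model: str
    a2: float
    c2: float
    d2: float
    e2: float
    total_variance: float
    mean: float
    loglik: float
    converged: bool
    boundary: dict


def twin_pairs_from_pedigree(
    values: pd.Series | np.ndarray, ped: pd.DataFrame, sample_ids=None
) -> TwinPairSet:
    """Assemble complete twin pairs for one site from pedigree structure.

    Twin ordering within a pair is fixed by sample id.  Pairs with a
    missing value in either member are dropped.
    """
    if isinstance(values, pd.Series):
        series = values
    else:
        series = pd.Series(np.asarray(values, float), index=list(sample_ids))
    twins = ped[ped["role"].isin(["mz_twin", "dz_twin"])]
    mz_rows, dz_rows = [], []
    for (_, zyg), members in twins.groupby(["family_id", "zygosity"], sort=True):
        ids = sorted(members["sample_id"])
        if len(ids) != 2:
            continue
        pair = series.reindex(ids).to_numpy(float)
        if np.isnan(pair).any():
            continue
        (mz_rows if zyg == "MZ" else dz_rows).append(pair)
    return TwinPairSet(
        mz=np.array(mz_rows).reshape(-1, 2),
        dz=np.array(dz_rows).reshape(-1, 2),
    )


def twin_correlations(pairs: TwinPairSet) -> TwinCorrelations:
    """Pearson correlation per zygosity group."""

    def _corr(arr, label):
        if arr.shape[0] < 3:
            raise ValueError(f"need >=3 {label} pairs for a correlation")
        if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
            raise ValueError(f"zero variance within {label} pairs; correlation undefined")
        return float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])

    return TwinCorrelations(
        rmz=_corr(pairs.mz, "MZ"),
        rdz=_corr(pairs.dz, "DZ"),
        n_mz=pairs.n_mz,
        n_dz=pairs.n_dz,
    )


def falconer_h2(rc: TwinCorrelations) -> tuple[float, bool]:
    """Falconer estimate h2_twins = 2 (rMZ - rDZ); returns (h2, out_of_bounds)."""
    h2 = 2.0 * (rc.rmz - rc.rdz)
    return h2, not (0.0 <= h2 <= 1.0)


# ---------------------------------------------------------------------------
# maximum-likelihood twin models
# ---------------------------------------------------------------------------


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    y = np.maximum(y, 1e-12)
    return y + np.log1p(-np.exp(-y))


def _group_nll(arr, mu, v, cov):
    """NLL of n pairs under a bivariate normal with equal variances v and covariance cov."""
    n = arr.shape[0]
    if n == 0:
        return 0.0
    det = v * v - cov * cov
    if det <= 0 or v <= 0:
        return np.inf
    r1 = arr[:, 0] - mu
    r2 = arr[:, 1] - mu
    s11 = r1 @ r1
    s22 = r2 @ r2
    s12 = r1 @ r2
    quad = (v * (s11 + s22) - 2.0 * cov * s12) / det
    return 0.5 * (n * np.log(det) + quad) + n * np.log(2.0 * np.pi)


def _expected_covs(model, va, vc, vd):
    if model == "ACE" or model == "AE" or model == "CE" or model == "E":
        return va + vc, 0.5 * va + vc
    if model == "ADE":
        return va + vd, 0.5 * va + 0.25 * vd
    raise ValueError(f"unknown model {model!r}")


def fit_twin_model(
    pairs: TwinPairSet,
    model: str = "ACE",
    min_pairs: int = 10,
    n_restarts: int = 3,
    seed: int = 0,
) -> TwinModelFit:
    """Fit a twin variance-component model by maximum likelihood.

    Free parameters are a shared mean and the standard deviations of the
    model's components (softplus-reparameterized to stay positive).  Uses
    quasi-Newton optimization with random restarts; the best solution by
    log-likelihood is returned, with components expressed as proportions of
    the fitted total variance.
    """
    model = model.upper()
    if model not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_COMPONENTS)}")
    if pairs.n_mz < min_pairs or pairs.n_dz < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} pairs per zygosity (got {pairs.n_mz} MZ, {pairs.n_dz} DZ)"
        )
    comps = MODEL_COMPONENTS[model]
    all_values = np.concatenate([pairs.mz.ravel(), pairs.dz.ravel()])
    tot_var = all_values.var(ddof=0)
    grand_mean = all_values.mean()
    if tot_var <= 0:
        raise ValueError("zero total variance; model undefined")

    def unpack(theta):
        mu = theta[0]
        sds = _softplus(theta[1:])
        v = dict.fromkeys("acde", 0.0)
        for name, sd in zip(comps, sds):
            v[name] = sd * sd
        return mu, v

    def nll(theta):
        mu, v = unpack(theta)
        cov_mz, cov_dz = _expected_covs(model, v["a"], v["c"], v["d"])
        total = v["a"] + v["c"] + v["d"] + v["e"]
        return _group_nll(pairs.mz, mu, total, cov_mz) + _group_nll(
            pairs.dz, mu, total, cov_dz
        )

    rng = np.random.default_rng(seed)
    k = len(comps)
    starts = [np.concatenate([[grand_mean], _inv_softplus(np.full(k, np.sqrt(tot_var / k)))])]
    for _ in range(n_restarts - 1):
        sds = np.sqrt(tot_var) * rng.uniform(0.2, 1.0, size=k)
        starts.append(np.concatenate([[grand_mean + rng.normal(0, 0.1)], _inv_softplus(sds)]))

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    mu, v = unpack(best.x)
    total = v["a"] + v["c"] + v["d"] + v["e"]
    props = {name: v[name] / total for name in "acde"}
    boundary = {name: bool(v[name] < _BOUNDARY_VAR) for name in comps}
    return TwinModelFit(
        model=model,
        a2=props["a"],
        c2=props["c"],
        d2=props["d"],
        e2=props["e"],
        total_variance=total,
        mean=mu,
        loglik=-float(best.fun),
        converged=converged,
        boundary=boundary,
    )


def likelihood_ratio_test(full: TwinModelFit, reduced: TwinModelFit):
    """LRT for nested twin models: 2*(ll_full - ll_reduced) ~ chi2(df).

    The degrees of freedom equal the difference in the number of variance
    components; the chi-square reference is conventional and conservative
    when the tested component sits on the zero boundary.
    """
    comps_full = set(MODEL_COMPONENTS[full.model])
    comps_red = set(MODEL_COMPONENTS[reduced.model])
    if not comps_red < comps_full:
        raise ValueError(
            f"{reduced.model} is not nested in {full.model}; LRT undefined"
        )
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(comps_full) - len(comps_red)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p
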