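"""Twin-family methylome simulator with known ground truth.

Generates pedigrees of MZ/DZ twin pairs (optionally with parents and
siblings), gene-drops biallelic SNP genotypes through them, and builds
per-site methylation values (M scale) from a configurable variance
decomposition:

- ``var_snp``   additive variance tagged by genotyped causal SNPs,
- ``var_ped``   additive polygenic variance not tagged by the SNP panel,
- ``var_c``     common (family-shared) environment,
- ``var_d``     dominance (non-additive genetic) variance,
- ``var_e``     unique environment.

Genetic sharing follows the standard expectations: MZ co-twins share all
additive and dominance deviations, first-degree relatives share additive
deviations with coefficient 0.5 and (for siblings/DZ twins) dominance
deviations with coefficient 0.25.  Genetic and environmental standard
deviations may be linear functions of z-scored age or of sex (0/1), which
is the generative counterpart of the variance-moderation models fitted by
:mod:`methvc.moderation`.

Default cohort parameters emulate a large adult twin register: 769 MZ and
424 DZ pairs, mean age 37.2 (s.d. 13.3, range 17-79), 66% female.  The
``desk_config`` preset (200 MZ + 200 DZ pairs, 500 SNPs, 50 sites) keeps
simulation-based tests fast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SiteParams",
    "ConfigurationError",
    "desk_config",
    "random_site_params",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_site",
    "simulate_annotation",
    "generate_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SiteParams:
    """Ground-truth variance decomposition of one methylation site.

    Variance fractions refer to the moderator value 0 (the cohort-mean age
    and, for sex moderation, males) and must sum to 1 there.  Moderation
    slopes act on component *standard deviations*: the additive-genetic
    s.d. at moderator value m is ``sqrt(var_ped) + beta_g * m`` and the
    unique-environment s.d. is ``sqrt(var_e) + beta_e * m``.
    """

    var_snp: float = 0.07
    var_ped: float = 0.12
    var_c: float = 0.03
    var_d: float = 0.0
    var_e: float = 0.78
    n_causal: int = 20
    beta_g_age: float = 0.0
    beta_e_age: float = 0.0
    beta_g_sex: float = 0.0
    beta_e_sex: float = 0.0
    baseline_beta: float = 0.5

    def validate(self) -> None:
        fracs = (self.var_snp, self.var_ped, self.var_c, self.var_d, self.var_e)
        if any(v < 0 for v in fracs):
            raise ConfigurationError("variance fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-8:
            raise ConfigurationError(
                f"variance fractions must sum to 1 at moderator 0, got {sum(fracs):.6f}"
            )
        if not 0.0 < self.baseline_beta < 1.0:
            raise ConfigurationError("baseline_beta must lie in (0, 1)")
        if self.n_causal < 0:
            raise ConfigurationError("n_causal must be non-negative")
        moderated_g = self.beta_g_age != 0 or self.beta_g_sex != 0
        if moderated_g and self.var_ped == 0:
            raise ConfigurationError(
                "genetic moderation requires var_ped > 0 (the moderated component)"
            )
        moderated_e = self.beta_e_age != 0 or self.beta_e_sex != 0
        if moderated_e and self.var_e == 0:
            raise ConfigurationError("environmental moderation requires var_e > 0")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings; ``seed`` fully determines output."""

    n_mz_pairs: int = 769
    n_dz_pairs: int = 424
    n_parents: int = 212
    n_siblings: int = 16
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.01, 0.5)
    site_params: tuple[SiteParams, ...] = ()
    age_mean: float = 37.2
    age_sd: float = 13.3
    age_range: tuple[float, float] = (17.0, 79.0)
    prop_female: float = 0.66
    missing_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_parents", "n_siblings", "n_snps"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_mz_pairs + self.n_dz_pairs + self.n_parents + self.n_siblings == 0:
            raise ConfigurationError("configuration yields zero samples")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigurationError("age_range lower bound exceeds upper bound")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ConfigurationError("missing_rate must lie in [0, 0.5)")
        for p in self.site_params:
            p.validate()


def desk_config(n_sites: int = 50, seed: int = 0, **overrides) -> SimConfig:
    """Small preset (200 MZ + 200 DZ pairs, 500 SNPs) for fast test runs."""
    params = dict(
        n_mz_pairs=200,
        n_dz_pairs=200,
        n_parents=0,
        n_siblings=0,
        n_snps=500,
        site_params=random_site_params(n_sites, seed=seed + 1),
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def random_site_params(
    n_sites: int,
    seed: int = 0,
    n_causal: int = 20,
) -> tuple[SiteParams, ...]:
    """Draw per-site variance fractions from a Dirichlet centred on a
    methylome-like profile (mostly environmental, modest heritability)."""
    rng = np.random.default_rng(seed)
    # mean fractions ~ (snp .07, ped .12, c .03, d .03, e .75)
    alpha = np.array([0.7, 1.2, 0.3, 0.3, 7.5])
    fracs = rng.dirichlet(alpha, size=n_sites)
    baselines = np.clip(rng.beta(0.6, 0.6, size=n_sites), 0.05, 0.95)
    out = []
    for f, b in zip(fracs, baselines):
        f = f / f.sum()
        out.append(
            SiteParams(
                var_snp=f[0],
                var_ped=f[1],
                var_c=f[2],
                var_d=f[3],
                var_e=f[4],
                n_causal=n_causal,
                baseline_beta=float(b),
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = [
    "family_id",
    "sample_id",
    "father_id",
    "mother_id",
    "sex",
    "role",
    "zygosity",
    "age",
]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Build a twin-family pedigree table.

    Each family holds one twin pair; parents and full siblings are
    distributed round-robin over families.  MZ co-twins share sex and age;
    DZ co-twins share age with independently drawn sexes.  Sex is coded
    1=female, 0=male.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_fam = config.n_mz_pairs + config.n_dz_pairs
    if n_fam == 0:
        raise ConfigurationError("at least one twin family is required")

    fam_ids = [f"F{i + 1:05d}" for i in range(n_fam)]
    zygosity = ["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs
    twin_age = _truncated_normal(
        rng, config.age_mean, config.age_sd, *config.age_range, size=n_fam
    )

    # round-robin assignment of extra members
    fathers = set()
    mothers = set()
    for k in range(config.n_parents):
        fam = fam_ids[(k // 2) % n_fam]
        (fathers if k % 2 == 0 else mothers).add(fam)
    sib_count = {f: 0 for f in fam_ids}
    for k in range(config.n_siblings):
        sib_count[fam_ids[k % n_fam]] += 1

    rows = []
    for fam, zyg, age in zip(fam_ids, zygosity, twin_age):
        fid = f"{fam}_FA" if fam in fathers else "0"
        mid = f"{fam}_MO" if fam in mothers else "0"
        parent_age = age + rng.normal(28.0, 3.0)
        if fid != "0":
            rows.append([fam, fid, "0", "0", 0, "parent", "NA", parent_age])
        if mid != "0":
            rows.append([fam, mid, "0", "0", 1, "parent", "NA", parent_age])
        if zyg == "MZ":
            sex = int(rng.random() < config.prop_female)
            sexes = (sex, sex)
        else:
            sexes = (
                int(rng.random() < config.prop_female),
                int(rng.random() < config.prop_female),
            )
        role = "mz_twin" if zyg == "MZ" else "dz_twin"
        for t, sex in zip((1, 2), sexes):
            rows.append([fam, f"{fam}_T{t}", fid, mid, sex, role, zyg, age])
        for s in range(sib_count[fam]):
            sib_sex = int(rng.random() < config.prop_female)
            sib_age = max(config.age_range[0], age + rng.normal(0.0, 3.0))
            rows.append(
                [fam, f"{fam}_S{s + 1}", fid, mid, sib_sex, "sibling", "NA", sib_age]
            )

    ped = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)
    ped["age"] = ped["age"].round(1)
    if ped["sample_id"].duplicated().any():
        raise AssertionError("duplicate sample ids generated")
    return ped


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    ped: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-drop biallelic SNP genotypes through the pedigree.

    Founder haplotypes are drawn under Hardy-Weinberg equilibrium at MAFs
    uniform on ``config.maf_range``; offspring inherit one allele from each
    (possibly latent) parent by Mendelian transmission, with MZ co-twins
    receiving the identical transmission.

    Returns ``(genotypes, snp_info)`` where genotypes is a samples x SNPs
    dosage DataFrame (values 0/1/2) and snp_info holds id/chrom/pos/maf.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    n_snps = config.n_snps
    mafs = rng.uniform(*config.maf_range, size=n_snps)

    snp_info = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:06d}" for i in range(n_snps)],
            "chrom": "chr1",
            "pos": np.arange(1, n_snps + 1) * 2000,
            "maf": mafs,
        }
    )

    sample_ids = ped["sample_id"].tolist()
    dosages = np.zeros((len(sample_ids), n_snps), dtype=np.int8)
    row_of = {s: i for i, s in enumerate(sample_ids)}

    def founder_haplotypes():
        return (rng.random((2, n_snps)) < mafs).astype(np.int8)

    for fam, members in ped.groupby("family_id", sort=False):
        father_h = founder_haplotypes()
        mother_h = founder_haplotypes()
        # one realized transmission per offspring slot; MZ twins share slot 0
        def transmit():
            pick_f = rng.integers(0, 2, size=n_snps)
            pick_m = rng.integers(0, 2, size=n_snps)
            return father_h[pick_f, np.arange(n_snps)] + mother_h[
                pick_m, np.arange(n_snps)
            ]

        twins = members[members["role"].isin(["mz_twin", "dz_twin"])]
        mz = (twins["zygosity"] == "MZ").any()
        shared = transmit() if mz else None
        for _, person in members.iterrows():
            i = row_of[person["sample_id"]]
            if person["role"] == "parent":
                h = father_h if person["sex"] == 0 else mother_h
                dosages[i] = h.sum(axis=0)
            elif person["role"] == "mz_twin":
                dosages[i] = shared
            else:  # dz twin or sibling
                dosages[i] = transmit()

    genotypes = pd.DataFrame(dosages, index=sample_ids, columns=snp_info["snp_id"])
    genotypes.index.name = "sample_id"
    return genotypes, snp_info


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def simulate_covariates(ped: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-sample covariates: sex, age, array row, plate, white-cell percentages.

    Array rows (6 per chip) and 96-well plates are assigned in sample order,
    emulating plating of whole families together; cell percentages are drawn
    around typical adult whole-blood values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    n = len(ped)
    cov = pd.DataFrame(
        {
            "sample_id": ped["sample_id"].to_numpy(),
            "sex": ped["sex"].to_numpy(),
            "age": ped["age"].to_numpy(),
            "array_row": (np.arange(n) % 6) + 1,
            "plate": [f"P{(i // 96) + 1:02d}" for i in range(n)],
            "neutrophil_pct": np.clip(rng.normal(55.0, 8.0, n), 20, 85),
            "monocyte_pct": np.clip(rng.normal(8.0, 2.0, n), 1, 20),
            "eosinophil_pct": np.clip(rng.normal(3.0, 1.5, n), 0, 12),
        }
    )
    return cov


# ---------------------------------------------------------------------------
# relatedness expectations within a family
# ---------------------------------------------------------------------------


def _family_relatedness(members: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Expected additive (2*kinship) and dominance relatedness within family."""
    roles = members["role"].to_numpy()
    zyg = members["zygosity"].to_numpy()
    k = len(members)
    add = np.eye(k)
    dom = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ri, rj = roles[i], roles[j]
            pair = {ri, rj}
            if ri == "mz_twin" and rj == "mz_twin" and zyg[i] == "MZ":
                a, d = 1.0, 1.0
            elif pair <= {"mz_twin", "dz_twin", "sibling"}:
                # full sibs (incl. DZ twins, and a sib with one MZ twin)
                if ri == rj == "mz_twin":
                    a, d = 1.0, 1.0
                else:
                    a, d = 0.5, 0.25
            elif "parent" in pair and pair != {"parent"}:
                a, d = 0.5, 0.0
            elif pair == {"parent"}:
                a, d = 0.0, 0.0  # spouses
            else:  # pragma: no cover
                a, d = 0.0, 0.0
            add[i, j] = add[j, i] = a
            dom[i, j] = dom[j, i] = d
    return add, dom


# ---------------------------------------------------------------------------
# one site
# ---------------------------------------------------------------------------


def _moderator_scale(sigma: float, ages_z, sexes, beta_age: float, beta_sex: float):
    """Moderated s.d. profile s(m) = sigma + beta_age*age_z + beta_sex*sex."""
    return sigma + beta_age * np.asarray(ages_z) + beta_sex * np.asarray(sexes)


def simulate_site(
    ped: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    params: SiteParams,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one methylation site on the M scale for every sample.

    The value for individual i is

        mu + g_snp_i + g_ped_i * s_g(m_i)/s_g(0) + c_fam + d_i
           + e_i * s_e(m_i)/s_e(0)

    with the components scaled so that, at moderator value 0, the variance
    partition equals ``params`` exactly in expectation.  ``mu`` is the M
    value of ``params.baseline_beta``.
    """
    params.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ped = ped.reset_index(drop=True)
    n = len(ped)
    sample_ids = ped["sample_id"].to_numpy()
    cov = covariates.set_index("sample_id").loc[sample_ids]
    ages = cov["age"].to_numpy(float)
    sexes = cov["sex"].to_numpy(float)
    ages_z = (ages - ages.mean()) / ages.std(ddof=0)

    sigma_g = np.sqrt(params.var_ped)
    sigma_e = np.sqrt(params.var_e)
    s_g = _moderator_scale(sigma_g, ages_z, sexes, params.beta_g_age, params.beta_g_sex)
    s_e = _moderator_scale(sigma_e, ages_z, sexes, params.beta_e_age, params.beta_e_sex)
    if params.var_ped > 0 and s_g.min() < 0:
        raise ConfigurationError(
            "moderated genetic s.d. becomes negative over the sampled moderator range"
        )
    if params.var_e > 0 and s_e.min() <= 0:
        raise ConfigurationError(
            "moderated environmental s.d. becomes non-positive over the sampled range"
        )

    value = np.zeros(n)

    # SNP-tagged additive score from causal genotyped SNPs
    if params.var_snp > 0:
        if params.n_causal < 1:
            raise ConfigurationError("var_snp > 0 requires n_causal >= 1")
        n_causal = min(params.n_causal, genotypes.shape[1])
        causal = rng.choice(genotypes.shape[1], size=n_causal, replace=False)
        dos = genotypes.loc[sample_ids].to_numpy(float)[:, causal]
        p = dos.mean(axis=0) / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
        keep = sd > 0
        if not keep.any():
            raise ConfigurationError("all sampled causal SNPs are monomorphic")
        z = (dos[:, keep] - 2.0 * p[keep]) / sd[keep]
        score = z @ rng.normal(size=int(keep.sum()))
        score = score / score.std(ddof=0)
        value += np.sqrt(params.var_snp) * score

    # family-structured components drawn from expected relatedness
    fam_codes = ped.groupby("family_id", sort=False)
    for _, members in fam_codes:
        pos = members.index.to_numpy()  # positional: index reset above
        add, dom = _family_relatedness(members)
        k = len(pos)
        if params.var_ped > 0:
            L = np.linalg.cholesky(add + 1e-12 * np.eye(k))
            g = L @ rng.normal(size=k)
            value[pos] += np.sqrt(params.var_ped) * g * (s_g[pos] / sigma_g)
        if params.var_c > 0:
            value[pos] += np.sqrt(params.var_c) * rng.normal()
        if params.var_d > 0:
            L = np.linalg.cholesky(dom + 1e-12 * np.eye(k))
            value[pos] += np.sqrt(params.var_d) * (L @ rng.normal(size=k))

    if params.var_e > 0:
        e = rng.normal(size=n)
        value += np.sqrt(params.var_e) * e * (s_e / sigma_e)

    mu = np.log2(params.baseline_beta / (1.0 - params.baseline_beta))
    return mu + value


# ---------------------------------------------------------------------------
# toy genomic annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    n_sites: int, seed: int = 0, chrom_length: int = 20_000_000
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy single-chromosome annotation: site positions, genes and CGIs.

    Returns ``(sites, genes, cgis)``: site positions (1-based), a gene table
    (gene_id, chrom, strand, tss, end) and CGI intervals (chrom, start, end;
    1-based inclusive).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    n_genes = max(5, n_sites // 3)
    tss = np.sort(rng.choice(chrom_length, size=n_genes, replace=False)) + 1
    strand = rng.choice(["+", "-"], size=n_genes)
    length = rng.integers(2_000, 100_000, size=n_genes)
    end = np.where(strand == "+", tss + length, np.maximum(1, tss - length))
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(n_genes)],
            "chrom": "chr1",
            "strand": strand,
            "tss": tss,
            "end": end,
        }
    )
    n_cgi = max(3, n_sites // 5)
    starts = np.sort(rng.choice(chrom_length, size=n_cgi, replace=False)) + 1
    cgis = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + rng.integers(300, 2_000, size=n_cgi),
        }
    )
    # bias site placement toward promoters/CGIs so every class is populated
    pools = [
        rng.integers(1, chrom_length, size=n_sites),
        rng.choice(tss, size=n_sites) + rng.integers(-3_000, 1_000, size=n_sites),
        rng.choice(starts, size=n_sites) + rng.integers(-4_500, 4_500, size=n_sites),
    ]
    pick = rng.integers(0, 3, size=n_sites)
    pos = np.clip(np.choose(pick, pools), 1, chrom_length)
    sites = pd.DataFrame(
        {
            "site_id": [f"cg{i + 1:06d}" for i in range(n_sites)],
            "chrom": "chr1",
            "pos": np.sort(pos),
        }
    )
    return sites, genes, cgis


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a complete dataset and write it as TSV files.

    Writes pedigree, genotype dosages + SNP metadata, covariates, methylation
    on both M and beta scales (beta = 2^M / (1 + 2^M)), toy genomic
    annotation, and a truth table with every site's generative parameters.
    Missing methylation cells are injected completely at random at
    ``config.missing_rate`` and written as ``NA``.
    """
    config.validate()
    if not config.site_params:
        raise ConfigurationError("config.site_params is empty; nothing to simulate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ped = simulate_pedigree(config)
    genotypes, snp_info = simulate_genotypes(ped, config)
    covariates = simulate_covariates(ped, config)

    n_sites = len(config.site_params)
    sites, genes, cgis = simulate_annotation(n_sites, seed=config.seed)

    site_seeds = np.random.SeedSequence([config.seed, 23]).spawn(n_sites)
    m_values = np.empty((n_sites, len(ped)))
    for i, (params, ss) in enumerate(zip(config.site_params, site_seeds)):
        m_values[i] = simulate_site(
            ped, genotypes, covariates, params, seed=np.random.default_rng(ss)
        )

    if config.missing_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
        mask = rng.random(m_values.shape) < config.missing_rate
        m_values[mask] = np.nan

    meth_m = pd.DataFrame(
        m_values, index=sites["site_id"], columns=ped["sample_id"]
    )
    meth_m.index.name = "site_id"
    beta = np.power(2.0, m_values)
    beta = beta / (1.0 + beta)
    meth_beta = pd.DataFrame(beta, index=sites["site_id"], columns=ped["sample_id"])
    meth_beta.index.name = "site_id"

    truth = pd.DataFrame([dataclasses.asdict(p) for p in config.site_params])
    truth.insert(0, "site_id", sites["site_id"].to_numpy())

    paths = {
        "pedigree": outdir / "pedigree.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "snps": outdir / "snps.tsv",
        "covariates": outdir / "covariates.tsv",
        "methylation_m": outdir / "methylation_m.tsv",
        "methylation_beta": outdir / "methylation_beta.tsv",
        "sites": outdir / "sites.tsv",
        "genes": outdir / "genes.tsv",
        "cgis": outdir / "cgi.bed",
        "truth": outdir / "truth.tsv",
    }
    try:
        ped.to_csv(paths["pedigree"], sep="\t", index=False)
        genotypes.to_csv(paths["genotypes"], sep="\t")
        snp_info.to_csv(paths["snps"], sep="\t", index=False)
        covariates.to_csv(paths["covariates"], sep="\t", index=False)
        meth_m.to_csv(paths["methylation_m"], sep="\t", na_rep="NA", float_format="%.6g")
        meth_beta.to_csv(
            paths["methylation_beta"], sep="\t", na_rep="NA", float_format="%.6g"
        )
        sites.to_csv(paths["sites"], sep="\t", index=False)
        genes.to_csv(paths["genes"], sep="\t", index=False)
        # BED: 0-based half-open on disk
        bed = cgis.copy()
        bed["start"] = bed["start"] - 1
        bed.to_csv(paths["cgis"], sep="\t", index=False, header=False)
        truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing simulated dataset to {outdir}: {exc}") from exc
    return paths
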