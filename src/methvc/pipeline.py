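"""End-to-end orchestration: simulate/load -> QC -> residualize -> models -> catalogue.

``run_pipeline`` executes the stage sequence on either a simulated dataset
(from a :class:`methvc.simulate.SimConfig` block) or user-supplied TSV
files in the same formats, records every stage's parameters and outputs in
a JSON provenance file, and assembles the per-site catalogue.  A single
global seed fans out into per-stage child seeds so stages are individually
reproducible.  Sites whose model fit fails are emitted with a non-ok
status rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import kinship, moderation, preprocess, simulate, summaries, twin, varcomp

logger = logging.getLogger("methvc")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    output_dir: str = "methvc_run"
    seed: int = 0
    # either a simulate block or input file paths
    simulate: simulate.SimConfig | None = None
    inputs: dict = field(default_factory=dict)
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "qc": True,
        "twin": True,
        "grm": True,
        "moderation": True,
        "annotation": True,
    })
    # thresholds
    detp_max: float = 0.01
    min_beads: int = 3
    min_success: float = 0.95
    grm_maf_min: float = 0.01
    grm_cutoff: float = 0.05
    alpha: float = 0.05
    enrichment_family_size: int = 117
    h2_ages: tuple = (25.0, 50.0)
    log_level: str = "INFO"

    def validate(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.simulate is None:
            required = ["pedigree", "genotypes", "covariates", "methylation_m"]
            for key in required:
                path = self.inputs.get(key)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"input {key!r} missing or not found: {path}")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(open(path))
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        site_params = sim.pop("site_params", None)
        n_sites = sim.pop("n_sites", 50)
        if site_params is None:
            sim_cfg = simulate.SimConfig(**sim)
            site_params = simulate.random_site_params(n_sites, seed=sim_cfg.seed + 1)
            sim = {**sim, "site_params": site_params}
        else:
            sim["site_params"] = tuple(simulate.SiteParams(**p) for p in site_params)
        cfg.simulate = simulate.SimConfig(**sim)
    return cfg


def _child_seed(seed: int, stage: str) -> int:
    # stable across processes (unlike hash())
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns paths and the catalogue DataFrame."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"seed": config.seed, "stages": {}, "started": time.time()}

    def record(stage, **info):
        provenance["stages"][stage] = info

    # ---- stage: data -----------------------------------------------------
    if config.simulate is not None:
        logger.info("simulating dataset")
        paths = simulate.generate_dataset(config.simulate, outdir / "data")
        record("simulate", outputs={k: str(v) for k, v in paths.items()},
               n_sites=len(config.simulate.site_params))
    else:
        paths = {k: Path(v) for k, v in config.inputs.items()}
        record("load", inputs={k: str(v) for k, v in paths.items()})

    ped = pd.read_csv(paths["pedigree"], sep="\t", dtype={"father_id": str, "mother_id": str})
    genotypes = pd.read_csv(paths["genotypes"], sep="\t", index_col=0)
    covariates = pd.read_csv(paths["covariates"], sep="\t")
    meth = preprocess.MethylationMatrix.read_tsv(paths["methylation_m"], scale="m")

    # ---- stage: qc -------------------------------------------------------
    if config.stages.get("qc", True):
        qc_inputs = preprocess.ProbeQcInputs()
        for key, attr in (("detection_p", "detection_p"), ("bead_count", "bead_count")):
            if key in paths and Path(paths[key]).exists():
                setattr(qc_inputs, attr, pd.read_csv(paths[key], sep="\t", index_col=0))
        meth, report = preprocess.apply_probe_filters(
            meth, qc_inputs, detp_max=config.detp_max,
            min_beads=config.min_beads, min_success=config.min_success,
        )
        record("qc", **report.to_dict())

    meth = preprocess.impute_missing(meth, method="site_mean")

    # ---- stage: GRMs -----------------------------------------------------
    grm_ibs = kinship.compute_grm(genotypes, maf_min=config.grm_maf_min)
    grm_ibd = kinship.threshold_grm(grm_ibs, cutoff=config.grm_cutoff)
    grm_ped = kinship.pedigree_kinship(ped)
    pcs = kinship.genotype_pcs(grm_ibs, n_pcs=10)
    record("grm_build", n_snps=grm_ibs.n_snps, cutoff=config.grm_cutoff)

    # ---- stage: residualize + standardize --------------------------------
    design_with_pcs = preprocess.build_design(covariates, genotype_pcs=pcs,
                                              include_genotype_pcs=True)
    design_no_pcs = preprocess.build_design(covariates)
    resid_pcs, r2_pcs = preprocess.residualize(meth, design_with_pcs)
    resid_plain, _ = preprocess.residualize(meth, design_no_pcs)
    z_pcs = preprocess.zstandardize(resid_pcs)
    z_plain = preprocess.zstandardize(resid_plain)
    record("residualize", mean_r2=float(r2_pcs.mean()))

    sample_ids = list(meth.sample_ids)
    ped_idx = ped.set_index("sample_id").loc[sample_ids]
    fams = ped_idx["family_id"].to_numpy()
    cov_idx = covariates.set_index("sample_id").loc[sample_ids]

    site_ids = list(meth.site_ids)
    results: list[pd.DataFrame] = []

    # descriptive stats on the beta scale
    beta_vals = preprocess.beta_from_m(meth.values.to_numpy(float))
    desc = pd.DataFrame({
        "site_id": site_ids,
        "mean_beta": beta_vals.mean(axis=1),
        "sd_beta": beta_vals.std(axis=1, ddof=1),
    })
    results.append(desc)

    # ---- stage: twin models ---------------------------------------------
    if config.stages.get("twin", True):
        t0 = time.time()
        rows = []
        for i, site in enumerate(site_ids):
            y = z_plain.values.loc[site]
            row = {"site_id": site, "status_twin": "ok"}
            try:
                pairs = twin.twin_pairs_from_pedigree(y, ped)
                rc = twin.twin_correlations(pairs)
                h2f, flag = twin.falconer_h2(rc)
                ace = twin.fit_twin_model(pairs, "ACE", seed=_child_seed(config.seed, f"ace{i}"))
                ae = twin.fit_twin_model(pairs, "AE", seed=_child_seed(config.seed, f"ae{i}"))
                ce = twin.fit_twin_model(pairs, "CE", seed=_child_seed(config.seed, f"ce{i}"))
                _, _, p_a = twin.likelihood_ratio_test(ace, ce)
                _, _, p_c = twin.likelihood_ratio_test(ace, ae)
                row.update(rmz=rc.rmz, rdz=rc.rdz, h2_falconer=h2f,
                           falconer_out_of_bounds=flag,
                           a2=ace.a2, c2=ace.c2, e2=ace.e2, a2_ae=ae.a2,
                           p_A=p_a, p_C=p_c)
            except (ValueError, np.linalg.LinAlgError) as exc:
                row["status_twin"] = f"failed: {exc}"
            rows.append(row)
        results.append(pd.DataFrame(rows))
        record("twin", n_sites=len(site_ids), elapsed=time.time() - t0)

    # ---- stage: two-GRM model -------------------------------------------
    if config.stages.get("grm", True):
        t0 = time.time()
        rows = []
        for i, site in enumerate(site_ids):
            y = z_pcs.values.loc[site].to_numpy(float)
            row = {"site_id": site, "status_grm": "ok"}
            try:
                fit = varcomp.fit_two_grm(
                    y, grm_ibs, grm_ibd, seed=_child_seed(config.seed, f"grm{i}"),
                    compute_se=False,
                )
                row.update(sigma2_snp=fit.sigma2_snp, sigma2_ped=fit.sigma2_ped,
                           sigma2_e=fit.sigma2_e, h2=fit.h2_ibd,
                           h2_snps=fit.h2_snps, ratio_snp=fit.ratio_snp)
                if not fit.converged:
                    row["status_grm"] = "non_converged"
            except (ValueError, np.linalg.LinAlgError) as exc:
                row["status_grm"] = f"failed: {exc}"
            rows.append(row)
        results.append(pd.DataFrame(rows))
        record("two_grm", n_sites=len(site_ids), elapsed=time.time() - t0)

    # ---- stage: moderation ----------------------------------------------
    if config.stages.get("moderation", True):
        t0 = time.time()
        mod_age = moderation.moderator_from_age(cov_idx["age"].to_numpy(float))
        mod_sex = moderation.moderator_from_sex(cov_idx["sex"].to_numpy(float))
        alpha_adj = moderation.multiple_testing_threshold(config.alpha, len(site_ids))
        rows = []
        for i, site in enumerate(site_ids):
            y = z_pcs.values.loc[site].to_numpy(float)
            row = {"site_id": site, "status_moderation": "ok"}
            for tag, mod in (("age", mod_age), ("sex", mod_sex)):
                try:
                    fit = moderation.fit_moderation(
                        y, grm_ped, mod, families=fams,
                        seed=_child_seed(config.seed, f"mod{tag}{i}"),
                    )
                    row.update({
                        f"beta_g_{tag}": fit.beta_g, f"beta_e_{tag}": fit.beta_e,
                        f"se_beta_g_{tag}": fit.se_beta_g, f"se_beta_e_{tag}": fit.se_beta_e,
                        f"chi2_g_{tag}": fit.chi2_g, f"chi2_e_{tag}": fit.chi2_e,
                        f"p_g_{tag}": fit.p_g, f"p_e_{tag}": fit.p_e,
                        f"sig_g_{tag}": bool(np.isfinite(fit.p_g) and fit.p_g < alpha_adj),
                        f"sig_e_{tag}": bool(np.isfinite(fit.p_e) and fit.p_e < alpha_adj),
                    })
                    if tag == "age":
                        for age in config.h2_ages:
                            mval = moderation.age_to_moderator_value(fit, age)
                            row[f"h2_age{int(age)}"] = moderation.h2_at(fit, mval)
                    else:
                        row["h2_male"] = moderation.h2_at(fit, 0.0)
                        row["h2_female"] = moderation.h2_at(fit, 1.0)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    row["status_moderation"] = f"failed ({tag}): {exc}"
            rows.append(row)
        results.append(pd.DataFrame(rows))
        record("moderation", n_sites=len(site_ids), alpha_adjusted=alpha_adj,
               elapsed=time.time() - t0)

    # ---- stage: annotation ----------------------------------------------
    if config.stages.get("annotation", True) and "sites" in paths:
        sites_tab = pd.read_csv(paths["sites"], sep="\t")
        genes = pd.read_csv(paths["genes"], sep="\t")
        cgis = ann_mod.read_cgi_bed(paths["cgis"])
        annotated = ann_mod.annotate_sites(sites_tab, genes, cgis)
        annotated = annotated[annotated["site_id"].isin(site_ids)]
        ann_out = annotated[["site_id", "gene_region", "cgi_region"]].copy()
        ann_out["gene_region"] = ann_out["gene_region"].astype(str)
        ann_out["cgi_region"] = ann_out["cgi_region"].astype(str)
        results.append(ann_out)
        record("annotation", n_sites=len(ann_out))

    catalogue = summaries.write_catalogue(
        [r[r["site_id"].isin(site_ids)] for r in results], outdir / "catalogue.tsv"
    )

    # category flags where sources exist
    try:
        cats = ann_mod.categorize_sites(catalogue)
        cats.to_csv(outdir / "categories.tsv", sep="\t", index=False)
    except ValueError:
        pass

    provenance["finished"] = time.time()
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    logger.info("pipeline finished: %s", outdir / "catalogue.tsv")
    return {"catalogue": catalogue, "outdir": outdir, "provenance": provenance}
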