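"""Downstream summaries: repeated-measure correlations, EWAS-list overlap,
exposure-discordant MZ contrasts, and catalogue assembly.

These operations are deterministic transformations of per-site results:
longitudinal (or cross-tissue) stability of methylation, its coupling with
heritability, the interaction status of externally curated CpG lists
(smoking, BMI, lipids, metabolites, epigenetic-clock sites), and the
within-pair correlation contrast between exposure-concordant and
exposure-discordant MZ twin pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CpgList",
    "paired_site_correlations",
    "correlate_with_h2",
    "ewas_overlap",
    "discordant_mz_contrast",
    "write_catalogue",
    "read_catalogue",
]


@dataclass(frozen=True)
class CpgList:
    """Named CpG list (e.g. sites previously associated with smoking)."""

    name: str
    site_ids: tuple
    source: str = ""

    def __post_init__(self):
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids in CpG list")

    @classmethod
    def read(cls, path, name: str | None = None, source: str = "") -> "CpgList":
        """One id per line, or two-column TSV (site_id, source tag)."""
        rows = [ln.split("\t") for ln in open(path) if ln.strip()]
        ids = tuple(r[0].strip() for r in rows)
        if source == "" and rows and len(rows[0]) > 1:
            source = rows[0][1].strip()
        return cls(name=name or str(path), site_ids=ids, source=source)


def paired_site_correlations(
    first: pd.DataFrame, second: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.Series, dict]:
    """Per-site Pearson correlation between two repeated measures.

    ``first`` and ``second`` are sites x individuals matrices sharing index
    and columns (e.g. time point 1 vs time point 2, or blood vs buccal).
    Degenerate sites (zero variance or too few complete pairs) get NaN.
    Returns (per-site r, {'mean': ..., 'median': ..., 'n_sites': ...}).
    """
    if not first.index.equals(second.index) or not first.columns.equals(second.columns):
        raise ValueError("repeated-measure matrices must share sites and individuals")
    X = first.to_numpy(float)
    Y = second.to_numpy(float)
    r = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        ok = ~np.isnan(X[i]) & ~np.isnan(Y[i])
        if ok.sum() < min_pairs:
            continue
        x, y = X[i, ok], Y[i, ok]
        if x.std() == 0 or y.std() == 0:
            continue
        r[i] = np.corrcoef(x, y)[0, 1]
    r = pd.Series(r, index=first.index, name="r")
    if r.notna().sum() == 0:
        raise ValueError("all sites degenerate; no correlations computable")
    summary = {
        "mean": float(r.mean()),
        "median": float(r.median()),
        "n_sites": int(r.notna().sum()),
    }
    return r, summary


def correlate_with_h2(per_site_r: pd.Series, per_site_h2: pd.Series) -> float:
    """Genome-wide correlation of stability (r) with heritability over shared sites."""
    shared = per_site_r.index.intersection(per_site_h2.index)
    a = per_site_r.loc[shared]
    b = per_site_h2.loc[shared]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need >=3 shared sites with values")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def ewas_overlap(
    catalogue: pd.DataFrame, cpg_list: CpgList, interaction_flags: list[str] | None = None
) -> dict:
    """Overlap of an external CpG list with the catalogue's interaction flags.

    Counts, per boolean flag column (default: every column starting with
    ``sig_``), how many list sites carry the flag, and summarizes the
    heritability of the list sites.
    """
    if not cpg_list.site_ids:
        raise ValueError("empty CpG list")
    cat = catalogue.set_index("site_id")
    ids = pd.Index(cpg_list.site_ids)
    present = ids.intersection(cat.index)
    missing = ids.difference(cat.index)
    if interaction_flags is None:
        interaction_flags = [c for c in cat.columns if c.startswith("sig_")]
    sub = cat.loc[present]
    counts = {f: int(sub[f].fillna(False).astype(bool).sum()) for f in interaction_flags}
    out = {
        "list": cpg_list.name,
        "n_list": len(ids),
        "n_in_catalogue": len(present),
        "missing_ids": list(missing),
        "counts": counts,
    }
    for col in ("h2", "h2_ibd", "h2_snps"):
        if col in sub.columns and len(present):
            out[f"mean_{col}"] = float(sub[col].mean())
            out[f"sd_{col}"] = float(sub[col].std(ddof=1)) if len(present) > 1 else float("nan")
    return out


def discordant_mz_contrast(
    values: pd.DataFrame,
    mz_pairs: list[tuple[str, str]],
    exposure: pd.Series,
    site_ids=None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Within-pair correlation of MZ twins by exposure-concordance group.

    Pairs are split into concordant-exposed, concordant-unexposed and
    discordant groups by the binary ``exposure`` of the two co-twins; for
    each group the within-pair Pearson correlation is computed per site
    (twin 1 vs twin 2 across pairs) together with the group mean over
    sites.  Groups below ``min_pairs`` are omitted with a warning.
    """
    if site_ids is not None:
        values = values.loc[list(site_ids)]
    groups: dict[str, list[tuple[str, str]]] = {
        "concordant_exposed": [],
        "concordant_unexposed": [],
        "discordant": [],
    }
    for t1, t2 in mz_pairs:
        e1, e2 = bool(exposure.loc[t1]), bool(exposure.loc[t2])
        if e1 and e2:
            groups["concordant_exposed"].append((t1, t2))
        elif not e1 and not e2:
            groups["concordant_unexposed"].append((t1, t2))
        else:
            # put the exposed twin first for a consistent ordering
            groups["discordant"].append((t1, t2) if e1 else (t2, t1))

    rows = []
    for name, plist in groups.items():
        if len(plist) < min_pairs:
            warnings.warn(
                f"group {name} has {len(plist)} pairs (< {min_pairs}); omitted",
                stacklevel=2,
            )
            continue
        x = values[[p[0] for p in plist]].to_numpy(float)
        y = values[[p[1] for p in plist]].to_numpy(float)
        for site, xi, yi in zip(values.index, x, y):
            ok = ~np.isnan(xi) & ~np.isnan(yi)
            if ok.sum() < min_pairs or xi[ok].std() == 0 or yi[ok].std() == 0:
                r = np.nan
            else:
                r = np.corrcoef(xi[ok], yi[ok])[0, 1]
            rows.append({"group": name, "site_id": site, "r": r, "n_pairs": int(ok.sum())})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no group reached the minimum pair count")
    return out


CATALOGUE_SCHEMA_VERSION = "1"


def write_catalogue(tables: list[pd.DataFrame], path) -> pd.DataFrame:
    """Merge per-site result tables on site_id and write the catalogue TSV.

    Every table must contain a ``site_id`` column over the same site
    universe; conflicts (sites present in one table but not another) raise
    with the discrepancies listed.  The schema version is recorded in a
    header comment line.
    """
    if not tables:
        raise ValueError("no tables to merge")
    universe = set(tables[0]["site_id"])
    for t in tables[1:]:
        s = set(t["site_id"])
        if s != universe:
            raise ValueError(
                "conflicting site universes: "
                f"only_in_first={sorted(universe - s)[:5]}, only_in_other={sorted(s - universe)[:5]}"
            )
    merged = tables[0]
    for t in tables[1:]:
        overlap = [c for c in t.columns if c != "site_id" and c in merged.columns]
        merged = merged.merge(t.drop(columns=overlap), on="site_id", how="left")
    with open(path, "w") as fh:
        fh.write(f"# methvc catalogue schema v{CATALOGUE_SCHEMA_VERSION}\n")
        merged.to_csv(fh, sep="\t", index=False, na_rep="NA")
    return merged


def read_catalogue(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
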