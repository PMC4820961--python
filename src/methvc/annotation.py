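"""Gene-centric and CpG-island-centric annotation and enrichment tests.

Gene-centric classes, oriented by gene strand relative to the nearest TSS:

- proximal promoter: -1.5 kb to +500 bp of the TSS,
- distal promoter:   -10 kb to -1.5 kb,
- gene body:         +500 bp to the 3' end,
- downstream:        3' end to +5 kb past it,
- intergenic:        otherwise (in particular >10 kb from the nearest TSS).

Boundary positions belong to the more promoter-proximal class (a site at
exactly -1.5 kb is proximal promoter); nearest-TSS ties go to the lower
gene id.  CGI-centric classes: island (inside a CGI), shore (within 2 kb
of a CGI edge), shelf (2-4 kb), non-CGI beyond.  All coordinates are
1-based inclusive internally; BED inputs (0-based half-open) are shifted
on read.

Enrichment of a site category against a background is a per-class 2x2
Pearson chi-square without continuity correction, Bonferroni-controlled
over the test family (default 117 tests at alpha 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENE_REGIONS",
    "CGI_REGIONS",
    "assign_gene_region",
    "assign_cgi_region",
    "annotate_sites",
    "check_cgi_criteria",
    "categorize_sites",
    "enrichment_test",
    "read_cgi_bed",
]

GENE_REGIONS = ["proximal_promoter", "distal_promoter", "gene_body", "downstream", "intergenic"]
CGI_REGIONS = ["island", "shore", "shelf", "non_cgi"]

SHORE_BP = 2_000
SHELF_BP = 2_000


def _classify_by_gene(pos: int, tss: int, end: int, strand: str) -> str:
    """Class of one position relative to one gene's windows."""
    sign = 1 if strand == "+" else -1
    d = (pos - tss) * sign  # signed distance: negative = upstream
    gene_len = (end - tss) * sign
    if -1_500 <= d <= 500:
        return "proximal_promoter"
    if -10_000 <= d < -1_500:
        return "distal_promoter"
    if 500 < d <= gene_len:
        return "gene_body"
    if gene_len < d <= gene_len + 5_000:
        return "downstream"
    return "intergenic"


def assign_gene_region(chrom: str, pos: int, genes: pd.DataFrame) -> str:
    """Gene-centric region of a site, defined by its nearest TSS's gene.

    ``genes`` columns: gene_id, chrom, strand, tss, end.  Ties at equal TSS
    distance are broken by the lexicographically lower gene id.  A site on
    a chromosome absent from the table is labelled intergenic (with a
    warning).
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        warnings.warn(f"chromosome {chrom} absent from gene table; labelling intergenic",
                      stacklevel=2)
        return "intergenic"
    dist = (sub["tss"] - pos).abs()
    nearest = sub.loc[dist == dist.min()].sort_values("gene_id").iloc[0]
    return _classify_by_gene(pos, int(nearest["tss"]), int(nearest["end"]), nearest["strand"])


def assign_cgi_region(chrom: str, pos: int, cgis: pd.DataFrame) -> str:
    """CGI-centric region: island / shore (<=2 kb) / shelf (2-4 kb) / non-CGI.

    ``cgis`` columns: chrom, start, end (1-based inclusive, non-overlapping
    per chromosome); the nearest island governs.
    """
    sub = cgis[cgis["chrom"] == chrom]
    if sub.empty:
        return "non_cgi"
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    inside = (pos >= start) & (pos <= end)
    if inside.any():
        return "island"
    dist = np.minimum(np.abs(pos - start), np.abs(pos - end)).min()
    if dist <= SHORE_BP:
        return "shore"
    if dist <= SHORE_BP + SHELF_BP:
        return "shelf"
    return "non_cgi"


def annotate_sites(sites: pd.DataFrame, genes: pd.DataFrame, cgis: pd.DataFrame) -> pd.DataFrame:
    """Both annotation schemes for a site table (site_id, chrom, pos)."""
    gene_region = []
    cgi_region = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for chrom, pos in zip(sites["chrom"], sites["pos"]):
            gene_region.append(assign_gene_region(chrom, int(pos), genes))
            cgi_region.append(assign_cgi_region(chrom, int(pos), cgis))
    out = sites[["site_id", "chrom", "pos"]].copy()
    out["gene_region"] = pd.Categorical(gene_region, categories=GENE_REGIONS)
    out["cgi_region"] = pd.Categorical(cgi_region, categories=CGI_REGIONS)
    return out


def read_cgi_bed(path) -> pd.DataFrame:
    """Read CGI intervals from BED (0-based half-open) into 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                      names=["chrom", "start", "end"])
    bed["start"] = bed["start"] + 1
    return bed


def check_cgi_criteria(sequence: str) -> tuple[bool, dict]:
    """CpG-island test on a DNA sequence: GC > 50%, length > 200 bp,
    observed/expected CpG ratio > 0.6 (all strict).

    Observed = count of CG dinucleotides; expected = (#C * #G) / length.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains ambiguous bases")
    length = len(seq)
    n_c = seq.count("C")
    n_g = seq.count("G")
    gc_fraction = (n_c + n_g) / length if length else 0.0
    obs = sum(1 for i in range(length - 1) if seq[i : i + 2] == "CG")
    exp = (n_c * n_g) / length if length else 0.0
    obs_exp = obs / exp if exp > 0 else 0.0
    is_cgi = gc_fraction > 0.5 and length > 200 and obs_exp > 0.6
    return is_cgi, {"gc_fraction": gc_fraction, "length": length, "obs_exp_cpg": obs_exp}


# ---------------------------------------------------------------------------
# site categories and enrichment
# ---------------------------------------------------------------------------

CATEGORY_RULES = {
    "variable": ("sd_beta", ">", 0.03),
    "high_h2": ("h2", ">=", 0.5),
    "low_h2": ("h2", "<", 0.2),
    "high_h2snp": ("h2_snps", ">=", 0.5),
    "low_h2snp": ("h2_snps", "<", 0.2),
    "longitudinally_stable": ("longitudinal_r", ">=", 0.5),
    "longitudinally_unstable": ("longitudinal_r", "<", 0.2),
}


def categorize_sites(catalogue: pd.DataFrame) -> pd.DataFrame:
    """Boolean category flags per site from catalogue columns.

    Thresholds: variable sd_beta > 0.03 (strict); high h2 >= 0.5 / low
    h2 < 0.2 (likewise for h2_snps); longitudinally stable r >= 0.5 /
    unstable r < 0.2.  Rules whose source column is absent are skipped.
    """
    if "site_id" not in catalogue.columns:
        raise ValueError("catalogue must contain a site_id column")
    out = catalogue[["site_id"]].copy()
    applied = 0
    for flag, (col, op, thr) in CATEGORY_RULES.items():
        if col not in catalogue.columns:
            continue
        v = catalogue[col].astype(float)
        if op == ">":
            out[flag] = v > thr
        elif op == ">=":
            out[flag] = v >= thr
        else:
            out[flag] = v < thr
        out[flag] = out[flag] & v.notna()
        applied += 1
    if applied == 0:
        raise ValueError("no category source columns present in catalogue")
    return out


def enrichment_test(
    category_sites,
    background_sites,
    annotation: pd.DataFrame,
    scheme: str = "gene_region",
    alpha: float = 0.05,
    family_size: int = 117,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-class 2x2 chi-square enrichment of a category vs its background.

    For each region class the table cross-tabulates (in category) x (in
    class) over the background; Pearson chi-square without continuity
    correction by default.  Direction is 'enriched' when the category's
    class proportion exceeds the background's; significance is Bonferroni
    at ``alpha / family_size``.
    """
    category = set(category_sites)
    background = set(background_sites)
    if not category:
        raise ValueError("empty category")
    if not category <= background:
        raise ValueError("category sites must be a subset of the background")
    ann = annotation.set_index("site_id")[scheme]
    ann = ann.loc[ann.index.intersection(background)]
    in_cat = ann.index.isin(category)
    threshold = alpha / family_size
    rows = []
    for cls in ann.cat.categories if hasattr(ann, "cat") else sorted(ann.unique()):
        in_cls = (ann == cls).to_numpy()
        table = np.array(
            [
                [int((in_cat & in_cls).sum()), int((in_cat & ~in_cls).sum())],
                [int((~in_cat & in_cls).sum()), int((~in_cat & ~in_cls).sum())],
            ]
        )
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
        prop_cat = table[0, 0] / max(table[0].sum(), 1)
        prop_bg = in_cls.mean()
        rows.append(
            {
                "class": cls,
                "n_category": int(table[0, 0]),
                "n_background": int(in_cls.sum()),
                "prop_category": prop_cat,
                "prop_background": prop_bg,
                "chi2": chi2,
                "p": p,
                "direction": "enriched" if prop_cat > prop_bg else "depleted",
                "significant": bool(np.isfinite(p) and p < threshold),
            }
        )
    return pd.DataFrame(rows)
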