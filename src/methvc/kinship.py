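"""Genetic relationship matrices from genotypes and pedigrees.

``compute_grm`` builds the standard IBS-based GRM from standardized dosages
(the same estimator as the conventional whole-genome tools):

    A_jk = (1/N) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over SNPs with sample allele frequency MAF > ``maf_min``.  ``threshold_grm``
zeroes off-diagonal relationships below a cutoff (default 0.05, strict
inequality), yielding an IBD-like matrix in which only close relatives
retain nonzero relatedness.  ``pedigree_kinship`` builds the expected
additive relatedness (twice the kinship coefficient) from a pedigree table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Grm",
    "compute_grm",
    "threshold_grm",
    "pedigree_kinship",
    "genotype_pcs",
    "write_grm",
    "read_grm",
]


@dataclass
class Grm:
    """Symmetric sample x sample genetic relationship matrix."""

    sample_ids: list
    matrix: np.ndarray
    kind: str  # ibs | ibd_thresholded | pedigree_expected
    n_snps: int | None = None

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape does not match sample ids")
        if np.abs(m - m.T).max() > 1e-10:
            raise ValueError("GRM is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def compute_grm(
    genotypes: pd.DataFrame,
    maf_min: float = 0.01,
    founders_only_freq: bool = False,
    founder_ids=None,
) -> Grm:
    """IBS GRM from a samples x SNPs dosage matrix (0/1/2, NaN = missing).

    Allele frequencies are estimated from the full sample (including
    relatives) by default; pass ``founders_only_freq`` with ``founder_ids``
    to estimate them from founders.  Missing dosages contribute nothing and
    each pair is averaged over its observed SNP count.
    """
    X = genotypes.to_numpy(float)
    n, _ = X.shape
    obs = ~np.isnan(X)
    if founders_only_freq:
        if founder_ids is None:
            raise ValueError("founders_only_freq requires founder_ids")
        fmask = genotypes.index.isin(founder_ids)
        Xf, obsf = X[fmask], obs[fmask]
    else:
        Xf, obsf = X, obs
    with np.errstate(invalid="ignore"):
        p = np.nansum(np.where(obsf, Xf, 0.0), axis=0) / (2.0 * obsf.sum(axis=0))
    maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 SNPs pass the MAF>{maf_min} filter "
            "(input may be monomorphic)"
        )
    X, obs, p = X[:, keep], obs[:, keep], p[keep]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = np.where(obs, (X - 2.0 * p) / denom, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)  # pairwise observed SNPs
    A = (Z @ Z.T) / counts
    A = (A + A.T) / 2.0
    return Grm(
        sample_ids=list(genotypes.index),
        matrix=A,
        kind="ibs",
        n_snps=int(keep.sum()),
    )


def threshold_grm(grm: Grm, cutoff: float = 0.05) -> Grm:
    """Zero off-diagonal relationships strictly below ``cutoff``.

    Entries >= cutoff and the diagonal are untouched, turning the IBS matrix
    into an IBD-like matrix where unrelated individuals have exactly zero
    relatedness.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if grm.kind != "ibs":
        raise ValueError(f"expected an IBS GRM, got kind={grm.kind!r}")
    A = grm.matrix.copy()
    off = ~np.eye(A.shape[0], dtype=bool)
    A[off & (A < cutoff)] = 0.0
    return Grm(sample_ids=grm.sample_ids, matrix=A, kind="ibd_thresholded", n_snps=grm.n_snps)


def pedigree_kinship(ped: pd.DataFrame) -> Grm:
    """Expected additive relatedness (2 * kinship) from the pedigree table.

    Computed by the recursive kinship algorithm over the declared
    parent-offspring links, then patched so MZ co-twins are genetically
    identical (relatedness 1).  Diagonal is 1 (founders assumed outbred and
    unrelated).
    """
    ids = ped["sample_id"].tolist()
    idx = {s: i for i, s in enumerate(ids)}
    father = ped["father_id"].tolist()
    mother = ped["mother_id"].tolist()

    # topological order: parents before children
    order: list[int] = []
    state = {}

    def visit(i, stack):
        if state.get(i) == 2:
            return
        if i in stack:
            raise ValueError(f"pedigree cycle involving sample {ids[i]}")
        stack.add(i)
        for pid in (father[i], mother[i]):
            if pid in idx:
                visit(idx[pid], stack)
        stack.discard(i)
        state[i] = 2
        order.append(i)

    for i in range(len(ids)):
        visit(i, set())

    # latent shared parents: individuals in one family whose declared
    # parents are absent ("0") are full sibs if they share role context.
    # We rely on declared links plus zygosity/role to patch sib sharing.
    phi = np.zeros((len(ids), len(ids)))
    for i in order:
        fa = idx.get(father[i])
        mo = idx.get(mother[i])
        if fa is None and mo is None:
            phi[i, i] = 0.5
        else:
            pf = phi[fa, mo] if (fa is not None and mo is not None) else 0.0
            phi[i, i] = 0.5 * (1.0 + pf)
        for j in order:
            if j == i:
                break
            contrib = 0.0
            cnt = 0
            for par in (fa, mo):
                if par is not None:
                    contrib += phi[par, j]
                cnt += 1
            phi[i, j] = phi[j, i] = 0.5 * contrib

    A = 2.0 * phi
    np.fill_diagonal(A, 1.0)

    # undeclared-parent siblings: twins/sibs within a family with father_id
    # "0" still share latent parents; patch expected coefficients.
    roles = ped["role"].to_numpy()
    zyg = ped["zygosity"].to_numpy()
    for _, members in ped.groupby("family_id", sort=False):
        mi = [idx[s] for s in members["sample_id"]]
        for a_pos, i in enumerate(mi):
            for j in mi[a_pos + 1 :]:
                ri, rj = roles[i], roles[j]
                if {ri, rj} <= {"mz_twin", "dz_twin", "sibling"}:
                    if ri == rj == "mz_twin" and zyg[i] == "MZ":
                        A[i, j] = A[j, i] = 1.0
                    else:
                        A[i, j] = A[j, i] = 0.5
    return Grm(sample_ids=ids, matrix=A, kind="pedigree_expected")


def genotype_pcs(grm: Grm, n_pcs: int = 10) -> pd.DataFrame:
    """Top eigenvectors of the IBS GRM as genotype principal components."""
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:n_pcs]
    pcs = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(
        pcs, index=grm.sample_ids, columns=[f"PC{i + 1}" for i in range(len(order))]
    )


def write_grm(grm: Grm, prefix) -> None:
    """Write lower-triangle text GRM (id1 id2 n_snps value) plus an id list."""
    from pathlib import Path

    prefix = Path(prefix)
    ids = grm.sample_ids
    n_snps = grm.n_snps or 0
    with open(prefix.with_suffix(".grm.tsv"), "w") as fh:
        fh.write("id1\tid2\tn_snps\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{n_snps}\t{grm.matrix[i, j]:.8g}\n")
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        fh.write("\n".join(map(str, ids)) + "\n")


def read_grm(prefix, kind: str = "ibs") -> Grm:
    from pathlib import Path

    prefix = Path(prefix)
    ids = prefix.with_suffix(".grm.id").read_text().split()
    idx = {s: i for i, s in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    tab = pd.read_csv(prefix.with_suffix(".grm.tsv"), sep="\t")
    n_snps = int(tab["n_snps"].iloc[0]) if len(tab) else None
    for id1, id2, _, value in tab.itertuples(index=False):
        i, j = idx[str(id1)], idx[str(id2)]
        A[i, j] = A[j, i] = value
    return Grm(sample_ids=ids, matrix=A, kind=kind, n_snps=n_snps)
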