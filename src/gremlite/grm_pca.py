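"""Genomic relationship matrix and principal components.

The GRM entry for individuals j and k is

    f_jk = (1 / N_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

summed over the N_jk SNPs non-missing in both individuals, with p_i the
sample frequency of the counted allele.  Missing genotypes contribute
nothing to either the sum or the per-pair SNP count (no mean imputation).
Principal components for stratification adjustment are the top
eigenvectors of the GRM built from an LD-pruned SNP set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io_formats import MISSING, GenotypeData


@dataclass
class GRM:
    values: np.ndarray           # n x n symmetric
    pair_snp_counts: np.ndarray  # n x n
    ids: np.ndarray              # individual IDs
    fids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_snp_counts = np.asarray(self.pair_snp_counts, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.fids is None:
            self.fids = self.ids.copy()
        n = len(self.ids)
        if self.values.shape != (n, n) or self.pair_snp_counts.shape != (n, n):
            raise ValueError("GRM matrices must be n x n with n = len(ids)")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, iids) -> "GRM":
        """Restrict to the given individual IDs, in the given order."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in iids])
        return GRM(self.values[np.ix_(idx, idx)],
                   self.pair_snp_counts[np.ix_(idx, idx)],
                   self.ids[idx], self.fids[idx])


@dataclass
class PCScores:
    ids: np.ndarray
    eigenvectors: np.ndarray  # n x k, orthonormal columns
    eigenvalues: np.ndarray   # k, descending
    fids: np.ndarray = field(default=None)


def compute_grm(geno: GenotypeData, snps: list[str] | None = None) -> GRM:
    """GRM over all individuals, optionally restricted to a SNP ID list."""
    g = geno
    if snps is not None:
        mask = g.snp_meta["snp"].isin(snps).to_numpy()
        g = g.subset(snps=mask)
    d = g.dosages
    obs = d != MISSING
    p = g.allele1_freq()
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError(
            "monomorphic SNP reached GRM construction; apply the MAF filter first")
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (np.where(obs, d, 0).astype(float) - 2.0 * p) / denom
    z[~obs] = 0.0  # missing contributes nothing
    values = z @ z.T
    counts = obs.astype(float) @ obs.astype(float).T
    if (counts == 0).any():
        raise ValueError("pair of individuals with no shared non-missing SNPs")
    values /= counts
    return GRM(values, counts, g.iids.copy(),
               g.sample_meta["fid"].to_numpy().copy())


def compute_grm_naive(geno: GenotypeData) -> GRM:
    """Direct double-loop evaluation of the GRM formula (reference path).

    O(n^2 m); intended for cross-checking the vectorized implementation on
    small inputs.
    """
    d = geno.dosages
    n, m = d.shape
    obs = d != MISSING
    p = geno.allele1_freq()
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("monomorphic SNP in GRM input")
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    for j in range(n):
        for k in range(j, n):
            both = obs[j] & obs[k]
            nij = both.sum()
            if nij == 0:
                raise ValueError("pair with no shared non-missing SNPs")
            num = ((d[j, both] - 2 * p[both]) * (d[k, both] - 2 * p[both])
                   / (2 * p[both] * (1 - p[both]))).sum()
            values[j, k] = values[k, j] = num / nij
            counts[j, k] = counts[k, j] = nij
    return GRM(values, counts, geno.iids.copy(),
               geno.sample_meta["fid"].to_numpy().copy())


def pca_from_grm(grm: GRM, k: int = 10) -> PCScores:
    """Top-k eigenpairs of the GRM, eigenvalues descending.

    Eigenvector signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    n = grm.n
    if not 0 < k < n:
        raise ValueError("require 0 < k < n")
    if not np.allclose(grm.values, grm.values.T, atol=1e-8):
        raise ValueError("GRM is not symmetric")
    w, v = scipy.linalg.eigh(grm.values, subset_by_index=(n - k, n - 1))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    flip = v[np.abs(v).argmax(axis=0), np.arange(k)] < 0
    v[:, flip] *= -1.0
    return PCScores(ids=grm.ids.copy(), eigenvectors=v, eigenvalues=w,
                    fids=grm.fids.copy())
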