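"""Genotype quality control.

The filter chain mirrors standard cohort practice: individual call rate,
SNP call rate, minor allele frequency, Hardy-Weinberg exact test, LD
pruning (window/step/r^2), per-individual heterozygosity outliers computed
on the pruned SNP set, and removal of one member of each related pair found
by method-of-moments IBD estimation (pi-hat).  A second, looser LD pruning
pass produces the final analysis SNP set.

Filter order (individual call rate -> SNP call rate -> MAF -> HWE ->
LD prune -> heterozygosity -> IBD -> final re-prune) follows the order in
which the criteria are conventionally applied; every stage logs counts in,
removed, and counts out, and the counts telescope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .config import RunConfig, log
from .io_formats import MISSING, GenotypeData


@dataclass
class QCStage:
    name: str
    n_ind_in: int
    n_snp_in: int
    removed_individuals: list[str]
    removed_snps: list[str]

    @property
    def n_ind_out(self) -> int:
        return self.n_ind_in - len(self.removed_individuals)

    @property
    def n_snp_out(self) -> int:
        return self.n_snp_in - len(self.removed_snps)


@dataclass
class QCReport:
    stages: list[QCStage] = field(default_factory=list)

    def add(self, stage: QCStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            if (stage.n_ind_in, stage.n_snp_in) != (prev.n_ind_out, prev.n_snp_out):
                raise ValueError("QC stage counts do not telescope")
        self.stages.append(stage)
        log(stage.name, n_ind_in=stage.n_ind_in, n_snp_in=stage.n_snp_in,
            ind_removed=len(stage.removed_individuals),
            snp_removed=len(stage.removed_snps),
            n_ind_out=stage.n_ind_out, n_snp_out=stage.n_snp_out)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"stage": s.name, "n_ind_in": s.n_ind_in, "n_snp_in": s.n_snp_in,
             "ind_removed": len(s.removed_individuals),
             "snp_removed": len(s.removed_snps),
             "n_ind_out": s.n_ind_out, "n_snp_out": s.n_snp_out}
            for s in self.stages
        ])


@dataclass
class RelatednessEstimate:
    pair: tuple[str, str]
    ibd0: float
    ibd1: float
    ibd2: float

    @property
    def pi_hat(self) -> float:
        return self.ibd2 + 0.5 * self.ibd1


# ---------------------------------------------------------------------------
# call rate
# ---------------------------------------------------------------------------

def filter_call_rate(geno: GenotypeData, ind_threshold: float,
                     snp_threshold: float,
                     report: QCReport | None = None) -> GenotypeData:
    """Remove low-call-rate individuals first, then low-call-rate SNPs.

    The individual-first order means SNP call rates are computed on the
    individuals that survive the first step.
    """
    if not (0.0 <= ind_threshold <= 1.0 and 0.0 <= snp_threshold <= 1.0):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    obs = geno.dosages != MISSING
    ind_keep = obs.mean(axis=1) >= ind_threshold
    if not ind_keep.any():
        raise ValueError("all data removed by individual call-rate filter")
    snp_keep = obs[ind_keep].mean(axis=0) >= snp_threshold
    if not snp_keep.any():
        raise ValueError("all data removed by SNP call-rate filter")
    out = geno.subset(individuals=ind_keep, snps=snp_keep)
    if report is not None:
        report.add(QCStage(
            "call_rate", geno.n_individuals, geno.n_snps,
            list(geno.iids[~ind_keep]),
            list(geno.snp_meta["snp"].to_numpy()[~snp_keep])))
    return out


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def filter_maf(geno: GenotypeData, maf_min: float,
               report: QCReport | None = None) -> GenotypeData:
    """Keep SNPs with minor allele frequency >= maf_min (sample estimate)."""
    p = geno.allele1_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("all data removed by MAF filter")
    out = geno.subset(snps=keep)
    if report is not None:
        report.add(QCStage("maf", geno.n_individuals, geno.n_snps, [],
                           list(geno.snp_meta["snp"].to_numpy()[~keep])))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count whose conditional probability does not exceed that
    of the observed count (no mid-p correction).  Monomorphic samples
    return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = n_Aa + 2 * n_aa  # minor-allele count orientation is irrelevant
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log P(h | n, n_a) up to a constant: parity-matched enumeration
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1)
            - gammaln((n_a - hets) // 2 + 1)
            - gammaln((2 * n - n_a - hets) // 2 + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(hets, n_Aa)]
    return float(prob[prob <= p_obs * (1.0 + 1e-12)].sum())


def filter_hwe(geno: GenotypeData, p_min: float,
               report: QCReport | None = None) -> GenotypeData:
    """Keep SNPs whose HWE exact p-value is >= p_min."""
    d = geno.dosages
    obs = d != MISSING
    n_hom_a1 = ((d == 2) & obs).sum(axis=0)
    n_het = ((d == 1) & obs).sum(axis=0)
    n_hom_a2 = ((d == 0) & obs).sum(axis=0)
    pvals = np.array([hwe_exact_test(a, h, b)
                      for a, h, b in zip(n_hom_a1, n_het, n_hom_a2)])
    keep = pvals >= p_min
    if not keep.any():
        raise ValueError("all data removed by HWE filter")
    out = geno.subset(snps=keep)
    if report is not None:
        report.add(QCStage("hwe", geno.n_individuals, geno.n_snps, [],
                           list(geno.snp_meta["snp"].to_numpy()[~keep])))
    return out


# ---------------------------------------------------------------------------
# heterozygosity outliers
# ---------------------------------------------------------------------------

def heterozygosity_outliers(geno: GenotypeData, k: float) -> list[str]:
    """IDs of individuals with het rate outside mean +/- k*SD (ddof=1).

    Heterozygosity should be computed on an LD-pruned SNP set; pass the
    pruned subset.
    """
    if k <= 0:
        raise ValueError("SD multiple must be > 0")
    if geno.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    obs = geno.dosages != MISSING
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("individual with no non-missing genotypes")
    rate = (geno.dosages == 1).sum(axis=1) / n_obs
    sd = rate.std(ddof=1)
    if sd == 0:
        return []
    outlier = np.abs(rate - rate.mean()) > k * sd
    return list(geno.iids[outlier])


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _window_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, missing -> mean."""
    x = dos.astype(float)
    x[dos == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu, x) - mu
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # constant column correlates with nothing
    c = (x / sd).T @ (x / sd) / x.shape[0]
    return c ** 2


def ld_prune(geno: GenotypeData, window: int, step: int,
             r2_max: float) -> list[str]:
    """Greedy windowed LD pruning; returns retained SNP IDs in map order.

    Within each window of `window` SNPs (slid by `step`), while any pair of
    retained SNPs has r^2 > r2_max, the member with the lower MAF is removed
    (ties: the later map position).
    """
    if window < 2 or not 1 <= step <= window:
        raise ValueError("require window >= 2 and 1 <= step <= window")
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    m = geno.n_snps
    p = geno.allele1_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size < 2:
            continue
        r2 = _window_r2(geno.dosages[:, idx])
        active = np.ones(idx.size, dtype=bool)
        while True:
            sub = np.flatnonzero(active)
            offending = None
            for ii in range(sub.size):
                for jj in range(ii + 1, sub.size):
                    if r2[sub[ii], sub[jj]] > r2_max:
                        offending = (sub[ii], sub[jj])
                        break
                if offending:
                    break
            if offending is None:
                break
            a, b = offending
            # drop lower MAF; tie -> later map position (b)
            drop = a if maf[idx[a]] < maf[idx[b]] else b
            active[drop] = False
        keep[idx[~active]] = False
    return list(geno.snp_meta["snp"].to_numpy()[keep])


# ---------------------------------------------------------------------------
# IBD / relatedness
# ---------------------------------------------------------------------------

def estimate_ibd(geno: GenotypeData) -> list[RelatednessEstimate]:
    """Method-of-moments IBD estimates for every pair of individuals.

    Uses observed identity-by-state counts and sample allele frequencies
    (PLINK-style moments, no small-sample correction); probabilities are
    clamped to [0, 1] and renormalized.  Should be run on an LD-pruned set.
    """
    p = geno.allele1_freq()
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for IBD estimation")
    d = geno.dosages[:, poly]
    p = p[poly]
    q = 1.0 - p

    obs = (d != MISSING).astype(np.float64)
    i0 = ((d == 0) & (d != MISSING)).astype(np.float64)
    i1 = (d == 1).astype(np.float64)
    i2 = (d == 2).astype(np.float64)

    nonmiss = obs @ obs.T
    ibs0 = i0 @ i2.T + i2 @ i0.T
    ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    ibs1 = nonmiss - ibs0 - ibs2

    # per-SNP IBS-state probabilities conditional on IBD state
    e0_ibd0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibd1 = 2.0 * p * q
    e2_ibd1 = p**2 + q**2

    E0_0 = obs @ (obs * e0_ibd0).T
    E1_0 = obs @ (obs * e1_ibd0).T
    E2_0 = obs @ (obs * e2_ibd0).T
    E1_1 = obs @ (obs * e1_ibd1).T
    E2_1 = obs @ (obs * e2_ibd1).T

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0 / E0_0
        p1 = (ibs1 - p0 * E1_0) / E1_1
        p2 = (ibs2 - p0 * E2_0 - p1 * E2_1) / nonmiss

    ids = geno.iids
    out: list[RelatednessEstimate] = []
    n = geno.n_individuals
    for i in range(n):
        for j in range(i + 1, n):
            probs = np.clip([p0[i, j], p1[i, j], p2[i, j]], 0.0, 1.0)
            total = probs.sum()
            probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
            out.append(RelatednessEstimate((ids[i], ids[j]), *probs))
    return out


def remove_related(pairs: list[RelatednessEstimate], geno: GenotypeData,
                   pihat_max: float) -> list[str]:
    """Greedy relatedness pruning: keep the higher-call-rate member.

    Pairs with pi-hat > pihat_max are visited in list order; in each the
    member with the lower genotyping call rate is removed (tie: the
    later-listed member).  Pairs with an already-removed member are skipped.
    """
    if not 0.0 < pihat_max < 1.0:
        raise ValueError("pihat_max must be in (0, 1)")
    call = dict(zip(geno.iids, geno.call_rates()))
    removed: list[str] = []
    gone: set[str] = set()
    for est in pairs:
        if est.pi_hat <= pihat_max:
            continue
        a, b = est.pair
        if a in gone or b in gone:
            continue
        victim = b if call[a] >= call[b] else a
        gone.add(victim)
        removed.append(victim)
    return removed


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_qc(geno: GenotypeData, config: RunConfig | None = None):
    """Full QC chain; returns (final GenotypeData, pruned-IBD SNP IDs, QCReport).

    The returned genotype set is restricted to the final analysis pruning
    (prune_final); the second element is the tighter pruned SNP list used
    for heterozygosity, IBD and PCA.
    """
    cfg = config or RunConfig()
    report = QCReport()

    g = filter_call_rate(geno, cfg.ind_call_rate, cfg.snp_call_rate, report)
    g = filter_maf(g, cfg.maf_min, report)
    g = filter_hwe(g, cfg.hwe_p_min, report)

    pruned_ids = ld_prune(g, *cfg.prune_ibd)
    log("ld_prune_ibd", n_snp_in=g.n_snps, n_snp_kept=len(pruned_ids),
        window=cfg.prune_ibd[0], step=cfg.prune_ibd[1], r2=cfg.prune_ibd[2])
    pruned_mask = g.snp_meta["snp"].isin(pruned_ids).to_numpy()
    g_pruned = g.subset(snps=pruned_mask)

    het_out = heterozygosity_outliers(g_pruned, cfg.het_sd_mult)
    keep = ~np.isin(g.iids, het_out)
    report.add(QCStage("heterozygosity", g.n_individuals, g.n_snps, het_out, []))
    g = g.subset(individuals=keep)
    g_pruned = g_pruned.subset(individuals=keep)

    pairs = estimate_ibd(g_pruned)
    rel_out = remove_related(pairs, g, cfg.pihat_max)
    report.add(QCStage("relatedness", g.n_individuals, g.n_snps, rel_out, []))
    keep = ~np.isin(g.iids, rel_out)
    g = g.subset(individuals=keep)

    final_ids = ld_prune(g, *cfg.prune_final)
    final_mask = g.snp_meta["snp"].isin(final_ids).to_numpy()
    report.add(QCStage("ld_prune_final", g.n_individuals, g.n_snps, [],
                       list(g.snp_meta["snp"].to_numpy()[~final_mask])))
    g = g.subset(snps=final_mask)
    return g, pruned_ids, report
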