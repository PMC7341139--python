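"""Synthetic cohorts with known genetic architecture.

Genotypes are diploid biallelic dosages simulated at the haplotype level:
each SNP's ancestral allele frequency is drawn from a configurable MAF
range, population structure follows the Balding-Nichols model (subpopulation
frequencies Beta(p(1-FST)/FST, (1-p)(1-FST)/FST)), linkage disequilibrium is
a first-order allele-copy chain (copy the previous allele on the same
haplotype with probability rho, else draw fresh -> adjacent haplotype
r^2 ~= rho^2), and related pairs are built by explicit gamete transmission.

Phenotypes follow the additive polygenic model the downstream REML analysis
assumes: a set of causal SNPs shared across traits carries effect vectors
with across-trait covariance R_g, residuals have covariance R_e, and sex,
age and batch (platform/prefecture) effects enter the trait mean.  Causal
effects and residuals are rescaled by their realized standard deviations so
the realized heritability of every trait equals its target exactly, which
keeps desk-scale parameter-recovery tests tight.

Every operation takes its randomness from a numpy Generator derived from
the spec seed; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeData

RELATIONSHIPS = ("duplicate", "parent-offspring", "full-sib")


@dataclass
class GenoSimSpec:
    n: int = 500
    m: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    related_pairs: list[tuple[str, int]] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("LD rho must be in [0, 1)")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("FST must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        for rel, count in self.related_pairs:
            if rel not in RELATIONSHIPS:
                raise ValueError(f"unknown relationship {rel!r}")
            if count < 0:
                raise ValueError("pair count must be >= 0")


@dataclass
class GenoTruth:
    """Ground truth of a genotype simulation (never read by the pipeline)."""

    ancestral_freq: np.ndarray          # m
    subpop_freq: np.ndarray             # n_subpops x m
    subpop: np.ndarray                  # n, int labels
    pedigree: list[tuple[str, str, str]]  # (iid_a, iid_b, relationship)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ancestral_freq": self.ancestral_freq})
        for k in range(self.subpop_freq.shape[0]):
            df[f"subpop{k}_freq"] = self.subpop_freq[k]
        return df


def _transmit(hap_a: np.ndarray, hap_b: np.ndarray, rng) -> np.ndarray:
    """One gamete: per SNP, a random parental allele (unlinked transmission)."""
    pick = rng.integers(0, 2, size=hap_a.shape[0]).astype(bool)
    return np.where(pick, hap_a, hap_b)


def simulate_genotypes(spec: GenoSimSpec, rng: np.random.Generator | None = None):
    """Draw a GenotypeData and its GenoTruth under the spec's model."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m

    p_anc = rng.uniform(*spec.maf_range, size=m)
    if spec.n_subpops > 1 and spec.fst > 0.0:
        a = p_anc * (1.0 - spec.fst) / spec.fst
        b = (1.0 - p_anc) * (1.0 - spec.fst) / spec.fst
        p_sub = rng.beta(a, b, size=(spec.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)
    else:
        p_sub = np.tile(p_anc, (max(spec.n_subpops, 1), 1))
    subpop = rng.integers(0, max(spec.n_subpops, 1), size=n)

    # haplotypes: 2n x m, Markov allele-copy chain along SNPs
    p_hap = p_sub[np.repeat(subpop, 2)]  # 2n x m
    haps = np.empty((2 * n, m), dtype=np.uint8)
    haps[:, 0] = rng.random(2 * n) < p_hap[:, 0]
    if spec.ld_rho > 0.0:
        for j in range(1, m):
            fresh = rng.random(2 * n) < p_hap[:, j]
            copy = rng.random(2 * n) < spec.ld_rho
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    else:
        haps[:, 1:] = rng.random((2 * n, m - 1)) < p_hap[:, 1:]

    # inject related pairs into the last slots by gamete transmission
    pedigree: list[tuple[str, str, str]] = []
    iids = np.array([f"I{i:06d}" for i in range(n)])
    slot = n - 1
    for rel, count in spec.related_pairs:
        for _ in range(count):
            b, a = slot, slot - 1
            if a < 0:
                raise ValueError("more related pairs than available individuals")
            ha1, ha2 = haps[2 * a], haps[2 * a + 1]
            if rel == "duplicate":
                haps[2 * b] = ha1
                haps[2 * b + 1] = ha2
                subpop[b] = subpop[a]
            elif rel == "parent-offspring":
                haps[2 * b] = _transmit(ha1, ha2, rng)
                haps[2 * b + 1] = rng.random(m) < p_sub[subpop[a]]
                subpop[b] = subpop[a]
            else:  # full-sib: slots a and b become children of two fresh parents
                par = (rng.random((4, m)) < p_sub[subpop[a]]).astype(np.uint8)
                haps[2 * a] = _transmit(par[0], par[1], rng)
                haps[2 * a + 1] = _transmit(par[2], par[3], rng)
                haps[2 * b] = _transmit(par[0], par[1], rng)
                haps[2 * b + 1] = _transmit(par[2], par[3], rng)
                subpop[b] = subpop[a]
            pedigree.append((iids[a], iids[b], rel))
            slot -= 2

    dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
    if spec.missing_rate > 0.0:
        mask = rng.random((n, m)) < spec.missing_rate
        dosages[mask] = MISSING

    sex = np.where(rng.random(n) < 1.0 / 3.0, 1, 2)  # 1:2 male:female
    sample_meta = pd.DataFrame({
        "fid": [f"F{i:06d}" for i in range(n)],
        "iid": iids,
        "sex": sex,
        "platform": rng.choice([f"chip{k}" for k in range(1, 5)], size=n),
        "prefecture": rng.choice(["prefA", "prefB"], size=n),
    })
    snp_meta = pd.DataFrame({
        "chrom": 1,
        "snp": [f"snp{j:07d}" for j in range(m)],
        "pos": np.arange(1, m + 1) * 1000,
        "a1": "A",
        "a2": "G",
    })
    geno = GenotypeData(dosages, snp_meta, sample_meta)
    truth = GenoTruth(p_anc, p_sub, subpop, pedigree)
    return geno, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenoSimSpec:
    traits: list[str] = field(default_factory=lambda: ["trait1"])
    h2: list[float] = field(default_factory=lambda: [0.5])
    n_causal: int = 100
    rg: np.ndarray | None = None    # T x T genetic correlation targets
    re: np.ndarray | None = None    # T x T residual correlation targets
    sex_effect: list[float] | None = None        # added for females
    age_slope_male: list[float] | None = None    # per year of age
    age_slope_female: list[float] | None = None
    platform_effect_sd: float = 0.0
    prefecture_effect_sd: float = 0.0
    trait_mean: list[float] | None = None
    trait_sd: list[float] | None = None          # raw scale of the trait
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.traits)
        if len(self.h2) != t:
            raise ValueError("one h2 per trait required")
        if any(not 0.0 <= h <= 1.0 for h in self.h2):
            raise ValueError("h2 must lie in [0, 1]")
        for name in ("rg", "re"):
            mat = getattr(self, name)
            if mat is None:
                setattr(self, name, np.eye(t))
                continue
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (t, t) or not np.allclose(mat, mat.T):
                raise ValueError(f"{name} must be a symmetric {t}x{t} matrix")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"{name} must have unit diagonal")
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
            setattr(self, name, mat)
        for name in ("sex_effect", "age_slope_male", "age_slope_female",
                     "trait_mean"):
            if getattr(self, name) is None:
                setattr(self, name, [0.0] * t)
        if self.trait_sd is None:
            self.trait_sd = [1.0] * t


@dataclass
class PhenoTruth:
    genetic_values: np.ndarray      # n x T, on the unit-variance scale
    realized_h2: np.ndarray         # T
    realized_rg: np.ndarray         # T x T correlation of genetic values
    causal_idx: np.ndarray
    effects: np.ndarray             # n_causal x T


def _psd_factor(mat: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of semi-definite correlation targets."""
    w, v = np.linalg.eigh(mat)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_phenotypes(geno: GenotypeData, spec: PhenoSimSpec,
                        rng: np.random.Generator | None = None):
    """Draw a phenotype table and its PhenoTruth for a simulated cohort."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, m = geno.dosages.shape
    t = len(spec.traits)
    if spec.n_causal > m:
        raise ValueError("more causal SNPs requested than SNPs available")

    causal = np.sort(rng.choice(m, size=spec.n_causal, replace=False))
    dos = geno.dosages[:, causal].astype(float)
    dos[geno.dosages[:, causal] == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    col_sd = dos.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    z = (dos - col_mean) / col_sd

    effects = rng.standard_normal((spec.n_causal, t)) @ _psd_factor(spec.rg).T
    g = z @ effects
    g_sd = g.std(axis=0, ddof=1)
    g_sd[g_sd == 0] = 1.0
    g = g / g_sd * np.sqrt(spec.h2)

    resid = rng.standard_normal((n, t)) @ _psd_factor(spec.re).T
    r_sd = resid.std(axis=0, ddof=1)
    resid = resid / r_sd * np.sqrt(1.0 - np.asarray(spec.h2))

    sex = geno.sample_meta["sex"].to_numpy()
    is_female = sex == 2
    age = np.where(is_female, rng.uniform(17.0, 88.0, size=n),
                   rng.uniform(20.0, 90.0, size=n)).round(1)

    platform = geno.sample_meta["platform"].to_numpy()
    prefecture = geno.sample_meta["prefecture"].to_numpy()
    plat_levels = np.unique(platform)
    pref_levels = np.unique(prefecture)
    plat_eff = rng.normal(0.0, spec.platform_effect_sd or 0.0,
                          size=(len(plat_levels), t))
    pref_eff = rng.normal(0.0, spec.prefecture_effect_sd or 0.0,
                          size=(len(pref_levels), t))
    plat_idx = np.searchsorted(plat_levels, platform)
    pref_idx = np.searchsorted(pref_levels, prefecture)

    slope = np.where(is_female[:, None], np.asarray(spec.age_slope_female),
                     np.asarray(spec.age_slope_male))
    fixed = (np.asarray(spec.trait_mean)
             + is_female[:, None] * np.asarray(spec.sex_effect)
             + slope * age[:, None]
             + plat_eff[plat_idx] + pref_eff[pref_idx])

    values = fixed + (g + resid) * np.asarray(spec.trait_sd)

    if spec.outlier_rate > 0.0:
        hit = rng.random((n, t)) < spec.outlier_rate
        shift = rng.choice([-1.0, 1.0], size=(n, t)) * 10.0 * np.asarray(spec.trait_sd)
        values = np.where(hit, values + shift, values)

    pheno = geno.sample_meta[["fid", "iid", "sex", "prefecture", "platform"]].copy()
    pheno["age"] = age
    for j, name in enumerate(spec.traits):
        pheno[name] = values[:, j]

    realized_h2 = np.array([
        g[:, j].var(ddof=1) / (g[:, j] + resid[:, j]).var(ddof=1) for j in range(t)
    ])
    truth = PhenoTruth(
        genetic_values=g,
        realized_h2=realized_h2,
        realized_rg=np.corrcoef(g.T) if t > 1 else np.ones((1, 1)),
        causal_idx=causal,
        effects=effects,
    )
    return pheno, truth
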