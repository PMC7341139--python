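"""Readers and writers for the standard genotype / GRM / phenotype formats.

Genotypes travel as PLINK 1 binary filesets (.bed/.bim/.fam, SNP-major,
two bits per genotype).  Relationship matrices use the GCTA binary triple
(.grm.bin/.grm.N.bin/.grm.id, 4-byte little-endian floats over the lower
triangle including the diagonal).  Phenotype and covariate tables are
tab-separated text with a header and "NA" for missing values.

Dosage convention: entries count copies of allele1 from the .bim file
(the minor/effect allele under the PLINK default), so the 2-bit code 00
(homozygous allele1) decodes to dosage 2.  Missing genotypes are the
sentinel -1 in memory and "NA" in text output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # in-memory missing-dosage sentinel

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK code -> dosage of allele1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

SAMPLE_META_COLS = ["fid", "iid", "sex", "platform", "prefecture"]
SNP_META_COLS = ["chrom", "snp", "pos", "a1", "a2"]


@dataclass
class GenotypeData:
    """Diploid dosage matrix (individuals x SNPs) with SNP and sample metadata.

    dosages: int8 matrix with entries in {0, 1, 2, MISSING}.
    snp_meta: DataFrame with columns chrom, snp, pos (1-based), a1, a2.
    sample_meta: DataFrame with columns fid, iid, sex, platform, prefecture.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or the missing sentinel")
        if self.snp_meta["snp"].duplicated().any():
            raise ValueError("SNP identifiers must be unique")
        if self.sample_meta["iid"].duplicated().any():
            raise ValueError("individual IDs must be unique")
        for col in ("platform", "prefecture"):
            if col not in self.sample_meta.columns:
                self.sample_meta = self.sample_meta.copy()
                self.sample_meta[col] = "NA"
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def iids(self) -> np.ndarray:
        return self.sample_meta["iid"].to_numpy()

    def subset(self, individuals=None, snps=None) -> "GenotypeData":
        """Row/column subset by boolean mask or integer index array."""
        d = self.dosages
        sm = self.sample_meta
        vm = self.snp_meta
        if individuals is not None:
            idx = np.asarray(individuals)
            d = d[idx]
            sm = sm.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx]
        if snps is not None:
            idx = np.asarray(snps)
            d = d[:, idx]
            vm = vm.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx]
        return GenotypeData(d.copy(), vm.reset_index(drop=True), sm.reset_index(drop=True))

    def call_rates(self) -> np.ndarray:
        """Per-individual fraction of non-missing genotypes."""
        return (self.dosages != MISSING).mean(axis=1)

    def allele1_freq(self) -> np.ndarray:
        """Sample frequency of allele1 per SNP over non-missing calls."""
        obs = self.dosages != MISSING
        n_obs = obs.sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError("SNP with no non-missing calls")
        s = np.where(obs, self.dosages, 0).sum(axis=0)
        return s / (2.0 * n_obs)


# ---------------------------------------------------------------------------
# PLINK 1 binary fileset
# ---------------------------------------------------------------------------

def read_bed(path_prefix: str | Path) -> GenotypeData:
    """Read a PLINK .bed/.bim/.fam fileset (SNP-major v1.00 only)."""
    prefix = Path(path_prefix)
    bed, bim, fam = (Path(f"{prefix}{s}") for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    n, m = len(fam_df), len(bim_df)

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise ValueError(f"{bed}: not a PLINK 1 .bed file (bad magic bytes)")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise ValueError(
            f"{bed}: individual-major .bed layout (third byte 0x{raw[2]:02X}) "
            "is not supported; re-export in SNP-major order"
        )
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_snp:
        raise ValueError(
            f"{bed}: payload has {payload.size} bytes, expected "
            f"{m * bytes_per_snp} for {n} individuals x {m} SNPs"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # expand each byte into its four 2-bit codes (LSB pair = first individual)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # individuals x SNPs

    sample_meta = fam_df[["fid", "iid", "sex"]].copy()
    snp_meta = bim_df[SNP_META_COLS].copy()
    return GenotypeData(dosages, snp_meta, sample_meta)


def write_bed(geno: GenotypeData, path_prefix: str | Path) -> None:
    """Write a PLINK .bed/.bim/.fam fileset (SNP-major v1.00)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.dosages.shape

    fam = geno.sample_meta
    fam_cols = pd.DataFrame({
        "fid": fam["fid"], "iid": fam["iid"],
        "father": 0, "mother": 0,
        "sex": fam.get("sex", pd.Series([0] * n)), "pheno": -9,
    })
    fam_cols.to_csv(Path(f"{prefix}.fam"), sep="\t", header=False, index=False)

    bim = geno.snp_meta
    bim_cols = pd.DataFrame({
        "chrom": bim["chrom"], "snp": bim["snp"], "cm": 0,
        "pos": bim["pos"], "a1": bim["a1"], "a2": bim["a2"],
    })
    bim_cols.to_csv(Path(f"{prefix}.bim"), sep="\t", header=False, index=False)

    dos = geno.dosages.T  # SNP-major
    codes = np.where(dos == 2, 0b00,
             np.where(dos == 1, 0b10,
              np.where(dos == 0, 0b11, 0b01))).astype(np.uint8)
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(Path(f"{prefix}.bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# GCTA binary GRM triple
# ---------------------------------------------------------------------------

def write_grm_gcta(grm, path_prefix: str | Path) -> None:
    """Write a GRM as .grm.bin / .grm.N.bin / .grm.id.

    The value and count files hold the lower triangle (diagonal included)
    in row-major order as 4-byte little-endian floats; the ID file is
    two-column (FID, IID) tab-separated text.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(grm.values, dtype=np.float64)
    counts = np.asarray(grm.pair_snp_counts, dtype=np.float64)
    if not np.isfinite(values).all():
        raise ValueError("GRM contains non-finite entries")
    n = values.shape[0]
    tri = np.tril_indices(n)
    values[tri].astype("<f4").tofile(f"{prefix}.grm.bin")
    counts[tri].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    ids = pd.DataFrame({"fid": grm.fids, "iid": grm.ids})
    ids.to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(path_prefix: str | Path):
    """Read a GCTA-style binary GRM triple; returns a grm_pca.GRM."""
    from .grm_pca import GRM

    prefix = Path(path_prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    cnts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if vals.size != n_tri or cnts.size != n_tri:
        raise ValueError(
            f"{prefix}: triangle length {vals.size} does not match "
            f"{n} IDs (expected {n_tri})"
        )
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    tri = np.tril_indices(n)
    values[tri] = vals
    counts[tri] = cnts
    values = values + np.tril(values, -1).T
    counts = counts + np.tril(counts, -1).T
    return GRM(values=values, pair_snp_counts=counts,
               ids=ids["iid"].to_numpy(), fids=ids["fid"].to_numpy())


# ---------------------------------------------------------------------------
# phenotype / covariate tables
# ---------------------------------------------------------------------------

META_COLS = ["fid", "iid", "sex", "age", "prefecture", "platform"]


def trait_columns(pheno: pd.DataFrame) -> list[str]:
    """Columns of a phenotype table that hold trait values."""
    return [c for c in pheno.columns if c not in META_COLS]


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"fid": str, "iid": str})
    if df["iid"].duplicated().any():
        raise ValueError("duplicate individual IDs in phenotype table")
    if "age" in df.columns and (df["age"].dropna() < 0).any():
        raise ValueError("negative ages in phenotype table")
    return df


def write_phenotype_table(pheno: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def write_pc_scores(pcs, path: str | Path) -> None:
    """Eigenvector output: FID, IID, PC1..PCk tab-separated."""
    df = pd.DataFrame(pcs.eigenvectors,
                      columns=[f"PC{i+1}" for i in range(pcs.eigenvectors.shape[1])])
    df.insert(0, "iid", pcs.ids)
    df.insert(0, "fid", pcs.fids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
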