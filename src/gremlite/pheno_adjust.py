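"""Phenotype exclusions and sex-stratified age adjustment.

Participants with BMI below the floor (default 16 kg/m^2, the WHO 'severe
thinness' cut-off) are excluded from every trait; then, per trait and per
sex group, values beyond mean +/- k*SD (default k = 6) are set to missing
for that trait only, so each trait keeps its own sample size.  The REML
response is then built by regressing each trait on age within each sex
group by ordinary least squares and standardizing the residuals to
z-scores (mean 0, SD 1 per sex group, n-1 denominator).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import log
from .io_formats import trait_columns


def exclude_extremes(pheno: pd.DataFrame, bmi_floor: float | None = 16.0,
                     sd_mult: float = 6.0):
    """Apply the BMI floor and the per-sex +/- k*SD trait exclusion.

    Returns (filtered table, exclusion report DataFrame).  The BMI rule
    removes the participant from the whole table; the SD rule blanks the
    single offending trait value.  The SD statistic is computed after the
    BMI-floor removal, once (not iteratively).
    """
    if sd_mult <= 0:
        raise ValueError("sd_mult must be > 0")
    out = pheno.copy()
    records = []

    if bmi_floor is not None:
        if bmi_floor <= 0:
            raise ValueError("bmi_floor must be > 0")
        if "BMI" not in out.columns:
            raise ValueError("BMI column required when the BMI floor is active")
        low = out["BMI"].notna() & (out["BMI"] < bmi_floor)
        for iid in out.loc[low, "iid"]:
            records.append({"iid": iid, "trait": "<all>", "rule": "bmi_floor"})
        out = out.loc[~low].reset_index(drop=True)
        log("exclude_bmi", n_in=len(pheno), removed=int(low.sum()), n_out=len(out))

    traits = trait_columns(out)
    for trait in traits:
        for sex, grp in out.groupby("sex"):
            vals = grp[trait].dropna()
            if len(vals) < 2:
                continue
            mu, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0:
                continue
            extreme = grp[trait].notna() & ((grp[trait] - mu).abs() > sd_mult * sd)
            for iid in grp.loc[extreme, "iid"]:
                records.append({"iid": iid, "trait": trait, "rule": "sd_exclusion"})
            out.loc[grp.index[extreme], trait] = np.nan

    report = pd.DataFrame(records, columns=["iid", "trait", "rule"])
    log("exclude_sd", n_values_blanked=int((report["rule"] == "sd_exclusion").sum()))
    return out, report


def adjust_and_zscore(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Sex-stratified age regression residuals as z-scores.

    Within each sex group, the trait is regressed on intercept + age by
    OLS; residuals are divided by their sample SD (ddof=1).  Groups with
    zero age variance fall back to centering with a warning.  Returns a
    DataFrame (iid, sex, z) ordered by individual ID, restricted to
    non-missing observations.
    """
    if trait not in pheno.columns:
        raise KeyError(trait)
    rows = []
    for sex, grp in pheno.groupby("sex"):
        sub = grp.loc[grp[trait].notna() & grp["age"].notna()]
        if len(sub) < 3:
            raise ValueError(
                f"need >= 3 non-missing observations of {trait} in sex group {sex}")
        age = sub["age"].to_numpy(dtype=float)
        y = sub[trait].to_numpy(dtype=float)
        if np.ptp(age) == 0.0:
            warnings.warn(
                f"zero age variance in sex group {sex}; centering only",
                RuntimeWarning, stacklevel=2)
            resid = y - y.mean()
        else:
            X = np.column_stack([np.ones_like(age), age])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError(f"{trait} is constant in sex group {sex}")
        rows.append(pd.DataFrame({"iid": sub["iid"], "sex": sex, "z": resid / sd}))
    out = pd.concat(rows).sort_values("iid").reset_index(drop=True)
    return out


def adjust_all(pheno: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Wide table of adjusted z-scores (iid + one column per trait)."""
    traits = traits if traits is not None else trait_columns(pheno)
    wide = pheno[["iid"]].copy().sort_values("iid").reset_index(drop=True)
    for trait in traits:
        z = adjust_and_zscore(pheno, trait)[["iid", "z"]].rename(columns={"z": trait})
        wide = wide.merge(z, on="iid", how="left")
    return wide
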