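"""Correlation matrices, concordance statistics and figure exports.

Results are organized as paired triangles over a trait set: genetic
correlations (rg, with standard errors and significance marks) above the
diagonal, phenotypic correlations (rp) below.  The concordance analysis
compares the two triangles: the Pearson correlation between the vectors
of all pairwise rp and rg values, and the maximum absolute difference
|rg - rp| over pairs not involving an excluded trait set (typically the
low-heritability urinary biomarkers, whose rg estimates are noisy).

A reference table of published large-cohort estimates for 17
obesity-related traits ships with the package so the concordance
statistics can be recomputed without access to individual-level data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

TRAIT_GROUPS = {
    "cardiovascular": ["SBP", "DBP", "TG", "HDL-C"],
    "adiposity": ["wt", "BMI", "WC", "WHtR"],
    "renal": ["uCre", "uCl", "uK", "CysC", "SCre", "SUA", "BUN"],
}


def significance_mark(p: float) -> str:
    """Display convention: ** p<0.01, * p<0.05, + p<0.1."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


@dataclass
class CorrelationMatrices:
    """Paired rp/rg triangles over an ordered trait list."""

    traits: list[str]
    rg: np.ndarray      # T x T, symmetric storage, NaN diagonal
    rg_se: np.ndarray
    rp: np.ndarray
    sig: np.ndarray     # T x T object array of significance marks

    def __post_init__(self) -> None:
        t = len(self.traits)
        for name in ("rg", "rg_se", "rp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            setattr(self, name, arr)
        self.sig = np.asarray(self.sig, dtype=object)

    @property
    def n_pairs(self) -> int:
        t = len(self.traits)
        return t * (t - 1) // 2

    def pairs(self) -> pd.DataFrame:
        """Long format: one row per unordered trait pair (upper triangle)."""
        rows = []
        t = len(self.traits)
        for i in range(t):
            for j in range(i + 1, t):
                rows.append({
                    "trait1": self.traits[i], "trait2": self.traits[j],
                    "rp": self.rp[i, j], "rg": self.rg[i, j],
                    "rg_se": self.rg_se[i, j], "rg_sig": self.sig[i, j],
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_pairs(cls, df: pd.DataFrame,
                   traits: list[str] | None = None) -> "CorrelationMatrices":
        if traits is None:
            traits = list(pd.unique(df[["trait1", "trait2"]].to_numpy().ravel("K")))
        t = len(traits)
        idx = {name: i for i, name in enumerate(traits)}
        rg = np.full((t, t), np.nan)
        se = np.full((t, t), np.nan)
        rp = np.full((t, t), np.nan)
        sig = np.full((t, t), "", dtype=object)
        for row in df.itertuples(index=False):
            i, j = idx[row.trait1], idx[row.trait2]
            rg[i, j] = rg[j, i] = row.rg
            se[i, j] = se[j, i] = row.rg_se
            rp[i, j] = rp[j, i] = row.rp
            sig[i, j] = sig[j, i] = getattr(row, "rg_sig", "") or ""
        expected = t * (t - 1) // 2
        if len(df) != expected:
            raise ValueError(f"expected {expected} pairs for {t} traits, got {len(df)}")
        return cls(traits=list(traits), rg=rg, rg_se=se, rp=rp, sig=sig)


_REFERENCE_RESOURCE = "cohort_correlations_17traits.tsv"


def load_reference_correlations() -> CorrelationMatrices:
    """Packaged published estimates: 136 rg (+/- SE) and 136 rp over 17 traits."""
    ref = resources.files("gremlite.data").joinpath(_REFERENCE_RESOURCE)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#",
                         keep_default_na=False, na_values=[])
    df["rg_sig"] = df["rg_sig"].astype(str)
    for col in ("rg", "rg_se", "rp"):
        df[col] = df[col].astype(float)
    order = []
    for t1, t2 in zip(df["trait1"], df["trait2"]):
        for t in (t1, t2):
            if t not in order:
                order.append(t)
    return CorrelationMatrices.from_pairs(df, traits=order)


def concordance_stats(m: CorrelationMatrices,
                      exclude: set[str] | frozenset[str] = frozenset()) -> dict:
    """Phenotypic-vs-genetic correlation concordance.

    pearson_rp_rg uses ALL pairs; max_abs_diff is taken over pairs not
    involving an excluded trait.  The per-pair table (with diffs) feeds
    the scatter/regression export.
    """
    unknown = set(exclude) - set(m.traits)
    if unknown:
        raise ValueError(f"excluded traits not in the matrices: {sorted(unknown)}")
    df = m.pairs()
    if df[["rp", "rg"]].isna().any().any():
        raise ValueError("incomplete correlation matrices")
    df = df.assign(diff=df["rg"] - df["rp"])
    pearson = float(np.corrcoef(df["rp"], df["rg"])[0, 1])
    mask = ~(df["trait1"].isin(exclude) | df["trait2"].isin(exclude))
    max_abs = float(df.loc[mask, "diff"].abs().max())
    return {"pearson_rp_rg": pearson, "max_abs_diff": max_abs, "pairs": df}


def export_heatmap_data(m: CorrelationMatrices,
                        path_prefix: str | Path | None = None) -> pd.DataFrame:
    """Long-format heatmap table; optionally writes TSV + rendered figure."""
    df = m.pairs()
    if df[["rp", "rg"]].isna().any().any():
        raise ValueError("incomplete correlation matrices")
    if path_prefix is not None:
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(f"{prefix}_pairs.tsv", sep="\t", index=False)
        _render_heatmap(m, f"{prefix}_heatmap.png")
    return df


def _render_heatmap(m: CorrelationMatrices, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = len(m.traits)
    fig, axes = plt.subplots(1, 2, figsize=(14, 6))
    group_colors = {"cardiovascular": "green", "adiposity": "gold", "renal": "pink"}
    for ax, mat, title in ((axes[0], m.rp, "phenotypic (rp)"),
                           (axes[1], m.rg, "genetic (rg)")):
        shown = mat.copy()
        np.fill_diagonal(shown, 1.0)
        im = ax.imshow(shown, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(t), m.traits, rotation=90, fontsize=7)
        ax.set_yticks(range(t), m.traits, fontsize=7)
        ax.set_title(title)
        for gname, members in TRAIT_GROUPS.items():
            idx = [m.traits.index(x) for x in members if x in m.traits]
            if len(idx) >= 2 and idx == list(range(min(idx), max(idx) + 1)):
                lo, hi = min(idx) - 0.5, max(idx) + 0.5
                ax.add_patch(plt.Rectangle(
                    (lo, lo), hi - lo, hi - lo, fill=False,
                    edgecolor=group_colors[gname], linewidth=1.5))
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_scatter_regression(pairs: pd.DataFrame,
                              path_prefix: str | Path | None = None):
    """OLS of rg on rp over trait pairs; returns (slope, intercept, table)."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 trait pairs")
    rp = pairs["rp"].to_numpy(dtype=float)
    rg = pairs["rg"].to_numpy(dtype=float)
    if np.ptp(rp) == 0.0:
        raise ValueError("degenerate regression: all rp values equal")
    slope, intercept = np.polyfit(rp, rg, 1)
    table = pairs[["trait1", "trait2", "rp", "rg"]].copy()
    table["fitted"] = intercept + slope * rp
    if path_prefix is not None:
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(f"{prefix}_scatter.tsv", sep="\t", index=False)
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(rp, rg, s=18, alpha=0.8)
        xs = np.linspace(rp.min(), rp.max(), 50)
        ax.plot(xs, intercept + slope * xs, color="red",
                label=f"rg = {slope:.3f} rp + {intercept:.3f}")
        ax.set_xlabel("phenotypic correlation (rp)")
        ax.set_ylabel("genetic correlation (rg)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(f"{prefix}_scatter.png", dpi=120)
        plt.close(fig)
    return float(slope), float(intercept), table


def heritability_table(results: list[dict]) -> pd.DataFrame:
    """Assemble the per-trait summary (trait, h2, SE, P)."""
    return pd.DataFrame(results, columns=["trait", "h2", "SE", "P"])
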