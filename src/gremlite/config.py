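"""Run configuration: all pipeline thresholds and numerical settings.

Defaults: call rates >= 98%, MAF >= 1%, HWE exact p >= 1e-6, heterozygosity
outliers beyond 3 SD, pi-hat > 0.2 relatedness cutoff, LD pruning windows
(50, 5, 0.2) for IBD/PCA and (50, 5, 0.7) for the analysis set, BMI floor
16 kg/m^2 (the WHO severe-thinness line), +/- 6 SD phenotype exclusion,
10 principal components.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path


def log(stage: str, **kv) -> None:
    """Emit one machine-parsable key=value log line to stderr."""
    parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in kv.items()]
    print("[gremlite] " + " ".join(parts), file=sys.stderr)


@dataclass
class RunConfig:
    # genotype QC
    ind_call_rate: float = 0.98
    snp_call_rate: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    het_sd_mult: float = 3.0
    pihat_max: float = 0.2
    prune_ibd: tuple[int, int, float] = (50, 5, 0.2)
    prune_final: tuple[int, int, float] = (50, 5, 0.7)
    # phenotype exclusions
    sd_exclusion_mult: float = 6.0
    bmi_floor: float = 16.0
    # model
    n_pcs: int = 10
    reml_tol: float = 1e-4
    reml_max_iter: int = 100
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ind_call_rate", "snp_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0.0 < self.pihat_max < 1.0:
            raise ValueError("pihat_max must be in (0, 1)")
        for name in ("prune_ibd", "prune_final"):
            w, s, r2 = getattr(self, name)
            if w < 2 or not 1 <= s <= w or not 0.0 < r2 <= 1.0:
                raise ValueError(f"invalid pruning parameters {name}={(w, s, r2)}")

    # ---- flat key=value serialization ------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv.pop(f.name)
            if f.name.startswith("prune_"):
                w, s, r2 = raw.split(",")
                kwargs[f.name] = (int(w), int(s), float(r2))
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            else:
                kwargs[f.name] = float(raw)
        if kv:
            raise ValueError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)
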