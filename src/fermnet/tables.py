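"""Core tabular data containers and their tab-delimited serializations.

Two tables drive the pipeline: a fermentation time course (process
variables over time) and a metabolite peak-area table (samples x
metabolites with replicate / sampling-time annotations and one
internal-standard column). Both round-trip through plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "MetaboliteTable",
    "PhenotypeVector",
    "TIME_COL",
    "REPLICATE_COL",
]

TIME_COL = "time_h"
REPLICATE_COL = "replicate"

#: columns a time course must provide, in canonical order
_TC_REQUIRED = ("time_h", "od600", "dcw_g_l", "butanol_g_l")
_TC_OPTIONAL = ("acetate_g_l", "butyrate_g_l", "glucose_g_l", "ph")


@dataclass
class TimeCourse:
    """Sampled fermentation process variables over time.

    The time grid must be strictly increasing. OD and DCW positivity is
    enforced lazily by the rate estimators, which state where they need it.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TC_REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"time course missing required columns: {missing}")
        t = self.data["time_h"].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time course grid must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TimeCourse":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MetaboliteTable:
    """Samples x metabolites peak-area matrix with annotations.

    ``data`` holds one row per (time_h, replicate) sample; metabolite
    columns are everything except the two annotation columns. One column is
    designated the internal standard. ``kegg_ids`` optionally maps
    metabolite column names to KEGG-style compound ids.
    """

    data: pd.DataFrame
    internal_standard: str
    kegg_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in (TIME_COL, REPLICATE_COL):
            if col not in self.data.columns:
                raise ValueError(f"metabolite table missing annotation column {col!r}")
        if self.internal_standard not in self.data.columns:
            raise ValueError(
                f"internal-standard column {self.internal_standard!r} not in table"
            )
        keys = self.data[[TIME_COL, REPLICATE_COL]]
        if keys.duplicated().any():
            dupes = keys[keys.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (time, replicate) sample keys: {dupes}")
        a_s = self.data[self.internal_standard].to_numpy(dtype=float)
        if np.any(~np.isfinite(a_s)) or np.any(a_s <= 0):
            raise ValueError("internal-standard areas must be finite and > 0")

    @property
    def metabolites(self) -> list[str]:
        """Metabolite column names, internal standard excluded."""
        skip = {TIME_COL, REPLICATE_COL, self.internal_standard}
        return [c for c in self.data.columns if c not in skip]

    @property
    def sample_times(self) -> np.ndarray:
        """Sorted unique sampling times."""
        return np.sort(self.data[TIME_COL].unique())

    def areas(self) -> pd.DataFrame:
        """Peak-area matrix (samples x metabolites), annotations dropped."""
        return self.data[self.metabolites]

    def internal_standard_areas(self) -> np.ndarray:
        return self.data[self.internal_standard].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def kegg_map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": self.metabolites,
                "kegg_id": [self.kegg_ids.get(m, "NA") for m in self.metabolites],
            }
        )

    @classmethod
    def from_tsv(cls, path, internal_standard: str, kegg_map=None) -> "MetaboliteTable":
        data = pd.read_csv(path, sep="\t")
        kegg_ids: dict[str, str] = {}
        if kegg_map is not None:
            km = pd.read_csv(kegg_map, sep="\t")
            kegg_ids = {
                str(m): str(k)
                for m, k in zip(km["metabolite"], km["kegg_id"])
                if str(k) != "NA"
            }
        return cls(data, internal_standard=internal_standard, kegg_ids=kegg_ids)


@dataclass
class PhenotypeVector:
    """Per-sampling-time specific growth rate and specific butanol rate.

    Optionally carries the dry cell weight at each sampling time so that
    downstream normalization can reuse it.
    """

    time_h: np.ndarray
    mu: np.ndarray
    q: np.ndarray
    dcw_g_l: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.dcw_g_l is not None:
            self.dcw_g_l = np.asarray(self.dcw_g_l, dtype=float)
        n = len(self.time_h)
        if len(self.mu) != n or len(self.q) != n:
            raise ValueError("mu/q length must match sampling times")
        for arr, name in ((self.mu, "mu"), (self.q, "q")):
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.time_h, "mu_per_h": self.mu, "q_per_h": self.q})
        if self.dcw_g_l is not None:
            out["dcw_g_l"] = self.dcw_g_l
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeVector":
        df = pd.read_csv(path, sep="\t")
        dcw = df["dcw_g_l"].to_numpy() if "dcw_g_l" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["mu_per_h"].to_numpy(), df["q_per_h"].to_numpy(), dcw)
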