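"""Core data containers: interval-censored death tables and metabolite matrices.

Both containers wrap pandas DataFrames with validation and plain-CSV round trips,
so every pipeline stage can run from files or in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEATH_COLUMNS = ["vial", "interval_start", "interval_end", "n_dead", "n_censored"]
SAMPLE_COLUMNS = ["genotype_id", "age_day", "replicate", "block", "batch"]


@dataclass
class DeathTable:
    """Per-genotype death counts from scheduled observations.

    Deaths are only known to have occurred within an observation window
    ``[interval_start, interval_end)``; flies censored during a window are
    recorded in ``n_censored`` and treated as observed alive through
    ``interval_end``.

    Parameters
    ----------
    genotype_id : str
        Cohort label.
    data : pandas.DataFrame
        Columns ``vial, interval_start, interval_end, n_dead`` and optionally
        ``n_censored`` (missing column = no censoring).
    """

    genotype_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = {"vial", "interval_start", "interval_end", "n_dead"} - set(df.columns)
        if missing:
            raise ValueError(f"DeathTable missing columns: {sorted(missing)}")
        if "n_censored" not in df.columns:
            df["n_censored"] = 0
        df = df[DEATH_COLUMNS].reset_index(drop=True)
        if (df["interval_start"] >= df["interval_end"]).any():
            raise ValueError("interval_start must be < interval_end in every row")
        if (df["n_dead"] < 0).any() or (df["n_censored"] < 0).any():
            raise ValueError("counts must be non-negative")
        # non-overlap within vial
        for vial, grp in df.groupby("vial"):
            g = grp.sort_values("interval_start")
            if (g["interval_start"].values[1:] < g["interval_end"].values[:-1]).any():
                raise ValueError(f"overlapping intervals in vial {vial!r}")
        self.data = df

    @property
    def total_deaths(self) -> int:
        return int(self.data["n_dead"].sum())

    @property
    def total_censored(self) -> int:
        return int(self.data["n_censored"].sum())

    def aggregated(self) -> pd.DataFrame:
        """Counts pooled across vials, one row per (interval_start, interval_end)."""
        return (
            self.data.groupby(["interval_start", "interval_end"], as_index=False)[
                ["n_dead", "n_censored"]
            ]
            .sum()
            .sort_values("interval_start")
            .reset_index(drop=True)
        )

    def to_events(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to per-fly (duration, observed) arrays.

        Event times use the interval-end convention: a death recorded for
        ``[s, e)`` contributes duration ``e`` (the transfer day on which it
        was discovered); censored flies contribute ``e`` with observed=0.
        """
        agg = self.aggregated()
        durations, observed = [], []
        for _, row in agg.iterrows():
            durations.extend([row["interval_end"]] * int(row["n_dead"]))
            observed.extend([1] * int(row["n_dead"]))
            durations.extend([row["interval_end"]] * int(row["n_censored"]))
            observed.extend([0] * int(row["n_censored"]))
        return np.asarray(durations, dtype=float), np.asarray(observed, dtype=int)

    def merged_vials(self) -> "DeathTable":
        """Equivalent table with all vials pooled into one."""
        agg = self.aggregated()
        agg.insert(0, "vial", "pooled")
        return DeathTable(self.genotype_id, agg)


def write_death_tables(tables: dict[str, DeathTable], path) -> None:
    """Write a multi-genotype ``deaths.csv`` (genotype, vial, day, n_dead, ...)."""
    frames = []
    for gid in sorted(tables):
        df = tables[gid].data.copy()
        df.insert(0, "genotype", gid)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)


def read_death_tables(path) -> dict[str, DeathTable]:
    df = pd.read_csv(path)
    if "genotype" not in df.columns:
        raise ValueError(f"{path}: missing 'genotype' column")
    return {
        str(gid): DeathTable(str(gid), grp.drop(columns="genotype"))
        for gid, grp in df.groupby("genotype")
    }


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity matrix with sample metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        Indexed by sample_id with columns genotype_id, age_day, replicate,
        block, batch.
    values : pandas.DataFrame
        Indexed by sample_id, one column per metabolite. No missing values.
    normalized : bool
        True once rows have been log-transformed, centered, and scaled.
    qc_dropped : list of str
        Sample ids removed by preprocessing QC, with reasons.
    """

    samples: pd.DataFrame
    values: pd.DataFrame
    normalized: bool = False
    qc_dropped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if not self.samples.index.equals(self.values.index):
            raise ValueError("samples and values must share an identical index")
        if self.values.isna().any().any():
            raise ValueError("metabolite matrix contains missing values")
        if self.normalized:
            rows = self.values.to_numpy()
            if not (
                np.allclose(rows.mean(axis=1), 0.0, atol=1e-8)
                and np.allclose(rows.std(axis=1, ddof=1), 1.0, atol=1e-8)
            ):
                raise ValueError("normalized flag set but rows are not standardized")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, mask) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.samples.loc[mask].copy(),
            self.values.loc[mask].copy(),
            normalized=self.normalized,
            qc_dropped=list(self.qc_dropped),
        )

    def to_csv(self, path) -> None:
        wide = self.samples.join(self.values)
        wide.index.name = "sample_id"
        wide.to_csv(path)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "MetaboliteMatrix":
        wide = pd.read_csv(path, index_col="sample_id")
        missing = set(SAMPLE_COLUMNS) - set(wide.columns)
        if missing:
            raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
        meta = wide[SAMPLE_COLUMNS]
        vals = wide.drop(columns=SAMPLE_COLUMNS)
        return cls(meta, vals, normalized=normalized)
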