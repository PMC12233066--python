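"""Bootstrap cell-population profiling.

A condition's replicate wells are pooled (wells below a minimum cell count
are rejected, wells above a maximum are subsampled), then B bootstrap
samples of n cells are drawn with replacement.  Each sample is reduced to a
12-value profile: the mean and sample standard deviation of each of the six
per-cell descriptors.  Profiles are the rows of every downstream analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import Field, model_validator

from ._model import StrictModel, derive_seed, rng_from
from .morphometry import DESCRIPTORS, CellTable, descriptor_column

logger = logging.getLogger(__name__)

#: Fixed 12-feature layout: all means, then all SDs, in descriptor order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mean_{d}" for d in DESCRIPTORS] + [f"sd_{d}" for d in DESCRIPTORS]
)

#: Metadata columns carried alongside the features in ProfileMatrix CSVs.
META_COLUMNS: tuple[str, ...] = ("condition", "sample_index", "n_cells", "group")


class ProfilingConfig(StrictModel):
    """Bootstrap profiling parameters.

    Defaults follow the profiling design this package implements: 10
    bootstrap samples of 200 cells per condition, pooled from wells holding
    between 200 and 5000 cells each.
    """

    n: int = Field(default=200, ge=2, description="cells per bootstrap sample")
    n_bootstrap: int = Field(default=10, ge=1)
    min_cells_per_well: int = Field(default=200, ge=0)
    max_cells_per_well: int = Field(default=5000, ge=1)
    stratify_by_well: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ProfilingConfig":
        if self.min_cells_per_well > self.max_cells_per_well:
            raise ValueError("min_cells_per_well must be <= max_cells_per_well")
        return self


@dataclass(frozen=True)
class PopulationProfile:
    """12 summary statistics of one bootstrap cell-population sample."""

    condition: str
    sample_index: int
    features: dict[str, float]
    n_cells: int
    wells: tuple[str, ...] = ()
    seed: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        if tuple(self.features.keys()) != FEATURE_NAMES:
            raise ValueError(
                "profile features must be exactly the 12 canonical features "
                "in canonical order"
            )
        for name in FEATURE_NAMES:
            if name.startswith("sd_") and self.features[name] < 0:
                raise ValueError(f"negative SD feature {name}")

    def values(self) -> np.ndarray:
        return np.array([self.features[k] for k in FEATURE_NAMES])


def summarize_population(
    sample: CellTable | pd.DataFrame,
    condition: str | None = None,
    sample_index: int = 0,
    seed: int = 0,
    group: str = "",
) -> PopulationProfile:
    """Reduce a sample of cells to its 12-feature population profile.

    Mean and sample standard deviation (n−1 denominator) of each of the six
    descriptors, in the canonical :data:`FEATURE_NAMES` order.

    Raises
    ------
    ValueError
        If the sample holds fewer than two cells (SD undefined).
    """
    df = sample.df if isinstance(sample, CellTable) else sample
    if len(df) < 2:
        raise ValueError("population summary requires at least 2 cells")
    feats: dict[str, float] = {}
    for d in DESCRIPTORS:
        feats[f"mean_{d}"] = float(df[descriptor_column(d)].to_numpy().mean())
    for d in DESCRIPTORS:
        feats[f"sd_{d}"] = float(df[descriptor_column(d)].to_numpy().std(ddof=1))
    cond = condition
    if cond is None:
        conds = pd.unique(df["condition"])
        cond = str(conds[0]) if len(conds) else "unknown"
    wells = tuple(str(w) for w in pd.unique(df["well_id"]))
    return PopulationProfile(
        condition=cond,
        sample_index=sample_index,
        features=feats,
        n_cells=len(df),
        wells=wells,
        seed=seed,
        group=group,
    )


def pool_condition(
    tables: Sequence[CellTable], cfg: ProfilingConfig | None = None
) -> CellTable:
    """Pool a condition's replicate wells into one cell pool.

    Wells with fewer than ``min_cells_per_well`` cells are rejected with a
    warning; wells with more than ``max_cells_per_well`` are subsampled to
    the maximum without replacement (seeded per well id, reproducible).

    Raises
    ------
    ValueError
        If no wells survive, naming the rejected wells.
    """
    cfg = cfg or ProfilingConfig()
    if not tables:
        raise ValueError("pool_condition requires at least one well")
    kept: list[CellTable] = []
    rejected: list[str] = []
    for t in tables:
        wells = ",".join(t.wells) or "<empty>"
        if len(t) < cfg.min_cells_per_well:
            logger.warning(
                "well %s rejected: %d cells < minimum %d",
                wells,
                len(t),
                cfg.min_cells_per_well,
            )
            rejected.append(wells)
            continue
        if len(t) > cfg.max_cells_per_well:
            rng = rng_from(derive_seed(cfg.seed, f"subsample:{wells}"))
            idx = np.sort(
                rng.choice(len(t), size=cfg.max_cells_per_well, replace=False)
            )
            logger.warning(
                "well %s subsampled from %d to %d cells",
                wells,
                len(t),
                cfg.max_cells_per_well,
            )
            t = CellTable(
                t.df.iloc[idx], t.calibration_um_per_px, dict(t.metadata)
            )
        kept.append(t)
    if not kept:
        raise ValueError(
            f"all wells rejected for this condition: {sorted(rejected)}"
        )
    return CellTable.concat(kept)


def bootstrap_profiles(
    pool: CellTable,
    cfg: ProfilingConfig | None = None,
    condition: str | None = None,
    group: str = "",
) -> list[PopulationProfile]:
    """Draw B bootstrap samples of n cells (with replacement) and summarize.

    Deterministic for a fixed (pool, cfg): the generator is seeded from
    ``cfg.seed``.  With ``stratify_by_well`` the n cells are allocated to
    wells proportionally to well size (largest-remainder rounding) and drawn
    with replacement within each well.
    """
    cfg = cfg or ProfilingConfig()
    n_pool = len(pool)
    if n_pool < cfg.n:
        raise ValueError(
            f"pool of {n_pool} cells is smaller than sample size n={cfg.n}"
        )
    rng = rng_from(cfg.seed)
    well_ids = pool.df["well_id"].to_numpy()
    profiles: list[PopulationProfile] = []
    for b in range(cfg.n_bootstrap):
        if cfg.stratify_by_well:
            idx = _stratified_indices(well_ids, cfg.n, rng)
        else:
            idx = rng.integers(0, n_pool, size=cfg.n)
        sample = pool.df.iloc[idx]
        profiles.append(
            summarize_population(
                sample,
                condition=condition,
                sample_index=b,
                seed=cfg.seed,
                group=group,
            )
        )
    return profiles


def _stratified_indices(
    well_ids: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    wells, counts = np.unique(well_ids, return_counts=True)
    quota = counts / counts.sum() * n
    alloc = np.floor(quota).astype(int)
    remainder = n - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:remainder]] += 1
    out: list[np.ndarray] = []
    for w, k in zip(wells, alloc):
        if k == 0:
            continue
        members = np.flatnonzero(well_ids == w)
        out.append(rng.choice(members, size=k, replace=True))
    return np.concatenate(out)


@dataclass
class ProfileMatrix:
    """Profiles × 12 features, with per-row condition metadata.

    ``features`` holds exactly the :data:`FEATURE_NAMES` columns in order;
    ``meta`` holds :data:`META_COLUMNS`, row-aligned with ``features``.
    """

    features: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.features.columns) != list(FEATURE_NAMES):
            raise ValueError("feature columns must match FEATURE_NAMES exactly")
        if self.features.isna().any().any():
            raise ValueError("profile matrix contains missing values")
        if len(self.features) != len(self.meta):
            raise ValueError("features and meta are misaligned")
        self.features = self.features.reset_index(drop=True)
        self.meta = self.meta.loc[:, list(META_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def values(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return self.meta["condition"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.meta["group"].to_numpy()

    def row_labels(self) -> list[str]:
        return [
            f"{c}#{i}"
            for c, i in zip(self.meta["condition"], self.meta["sample_index"])
        ]

    @classmethod
    def from_profiles(cls, profiles: Sequence[PopulationProfile]) -> "ProfileMatrix":
        if not profiles:
            raise ValueError("no profiles given")
        feats = pd.DataFrame(
            [[p.features[k] for k in FEATURE_NAMES] for p in profiles],
            columns=list(FEATURE_NAMES),
        )
        meta = pd.DataFrame(
            {
                "condition": [p.condition for p in profiles],
                "sample_index": [p.sample_index for p in profiles],
                "n_cells": [p.n_cells for p in profiles],
                "group": [p.group for p in profiles],
            }
        )
        return cls(feats, meta)

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.meta, self.features], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path)
        if "group" not in df.columns:
            df["group"] = ""
        df["group"] = df["group"].fillna("")
        return cls(df.loc[:, list(FEATURE_NAMES)], df.loc[:, list(META_COLUMNS)])

    def write_sidecar(self, path: str | Path, extra: Mapping | None = None) -> None:
        payload = {
            "feature_names": list(FEATURE_NAMES),
            "n_profiles": len(self),
            "conditions": sorted(set(map(str, self.conditions))),
        }
        payload.update(dict(extra or {}))
        Path(path).write_text(json.dumps(payload, indent=2))


def profile_conditions(
    tables_by_condition: Mapping[str, Sequence[CellTable]],
    cfg: ProfilingConfig | None = None,
) -> ProfileMatrix:
    """Pool and bootstrap-profile every condition; one seeded stream per
    condition so adding a condition does not perturb the others."""
    cfg = cfg or ProfilingConfig()
    profiles: list[PopulationProfile] = []
    for cond in tables_by_condition:
        sub = cfg.model_copy(
            update={"seed": derive_seed(cfg.seed, f"profile:{cond}")}
        )
        pool = pool_condition(list(tables_by_condition[cond]), sub)
        profiles.extend(
            bootstrap_profiles(pool, sub, condition=cond, group=str(cond))
        )
    return ProfileMatrix.from_profiles(profiles)
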