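"""Tabular domain containers: survey, environment, spatial layout, run configuration.

The survey is the raw community evidence — per-site, per-species counts of
individuals and wet biomass (kg), pooled over gears.  Environmental and
spatial tables are indexed by the same site labels.  All containers validate
on construction so downstream stages can assume consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurveyTable",
    "EnvironmentTable",
    "SpatialLayout",
    "RunConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def _check_unique(labels: Sequence, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what} labels: {dups}")


@dataclass
class SurveyTable:
    """Site x species counts and biomass.

    Parameters
    ----------
    count : pandas.DataFrame
        Integer individuals, rows = sites, columns = species.
    biomass : pandas.DataFrame
        Wet mass in kg, same shape/labels as ``count``.

    Invariants: labels unique; values non-negative; biomass > 0 requires
    count > 0 in the same cell.  Species with zero total count are dropped
    with a warning (they carry no information for any downstream stage).
    """

    count: pd.DataFrame
    biomass: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.count.index, "site")
        _check_unique(self.count.columns, "species")
        if not (self.count.index.equals(self.biomass.index)
                and self.count.columns.equals(self.biomass.columns)):
            raise ValidationError("count and biomass tables must share labels")
        cnt = self.count.to_numpy(dtype=float)
        bio = self.biomass.to_numpy(dtype=float)
        if np.any(cnt < 0) or np.any(bio < 0):
            raise ValidationError("negative count or biomass")
        if np.any(np.abs(cnt - np.round(cnt)) > 1e-9):
            raise ValidationError("counts must be integers")
        if np.any((bio > 0) & (cnt == 0)):
            bad = [
                (s, sp)
                for s in self.count.index
                for sp in self.count.columns
                if self.biomass.at[s, sp] > 0 and self.count.at[s, sp] == 0
            ]
            raise ValidationError(f"biomass without individuals at {bad[:5]}")
        empty = self.count.columns[self.count.sum(axis=0) == 0]
        if len(empty):
            warnings.warn(
                f"dropping {len(empty)} species with zero total count: "
                f"{list(empty)}", stacklevel=2)
            self.count = self.count.drop(columns=empty)
            self.biomass = self.biomass.drop(columns=empty)
        self.count = self.count.astype(int)
        for df in (self.count, self.biomass):
            df.index.name = "site"
            df.columns.name = "species"

    @property
    def sites(self) -> list[str]:
        return list(self.count.index)

    @property
    def species(self) -> list[str]:
        return list(self.count.columns)

    @property
    def n_sites(self) -> int:
        return self.count.shape[0]

    @property
    def n_species(self) -> int:
        return self.count.shape[1]

    def incidence(self) -> pd.DataFrame:
        """Presence/absence (bool) site x species matrix."""
        return self.count > 0

    def site_community(self, site: str) -> list[str]:
        """Species present at ``site``."""
        row = self.count.loc[site]
        return list(row.index[row > 0])

    def subset_species(self, species: Sequence[str]) -> "SurveyTable":
        keep = [s for s in self.species if s in set(species)]
        return SurveyTable(self.count[keep].copy(), self.biomass[keep].copy())


@dataclass
class EnvironmentTable:
    """Site x environmental-variable table (WT, pH, WD, NTU, nutrients, ...)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "site")
        _check_unique(self.values.columns, "variable")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValidationError(f"missing values in variables {bad}")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def nonconstant(self) -> "EnvironmentTable":
        """Drop zero-variance variables (with a warning); they cannot be standardized."""
        sd = self.values.std(axis=0, ddof=1)
        const = sd.index[(sd == 0) | sd.isna()].tolist()
        if const:
            warnings.warn(f"excluding constant variables: {const}", stacklevel=2)
            return EnvironmentTable(self.values.drop(columns=const))
        return self


@dataclass
class SpatialLayout:
    """River geometry: per-site distance to the dam and pairwise river distances (km).

    River distances are path lengths along the channel network; the triangle
    inequality is not assumed (a tributary junction can violate it relative
    to straight-line intuition), only symmetry and non-negativity.
    """

    dam_distance: pd.Series
    pair_distance: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dam_distance.index, "site")
        if not (self.pair_distance.index.equals(self.pair_distance.columns)
                and self.pair_distance.index.equals(self.dam_distance.index)):
            raise ValidationError("pair_distance labels must match dam_distance sites")
        m = self.pair_distance.to_numpy(dtype=float)
        if np.any(m < 0) or np.any(self.dam_distance.to_numpy(dtype=float) < 0):
            raise ValidationError("river distances must be non-negative")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("pair_distance must be symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-9):
            raise ValidationError("pair_distance diagonal must be zero")

    @property
    def sites(self) -> list[str]:
        return list(self.dam_distance.index)


@dataclass
class RunConfig:
    """Knobs for a full pipeline run.

    ``permutations`` feeds the tip-shuffle null (999 in the reference
    workflow; at least 99 for a meaningful standardized effect size).
    ``dominance_thresholds`` split the relative-importance index into
    dominant (> upper), common ([lower, upper]) and rare (< lower).
    """

    seed: int = 0
    permutations: int = 999
    dominance_thresholds: tuple[float, float] = (500.0, 100.0)
    alpha_level: float = 0.05
    align_policy: str = "strict"
    include_root: bool = True
    mantel_permutations: int = 999
    survey_path: str | None = None
    tree_path: str | None = None
    environment_path: str | None = None
    dam_distance_path: str | None = None
    pair_distance_path: str | None = None
    out_dir: str = "results"
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.permutations < 99:
            raise ValidationError("permutations must be >= 99")
        hi, lo = self.dominance_thresholds
        if not hi > lo:
            raise ValidationError("dominance thresholds must be strictly ordered")
        if self.align_policy not in ("strict", "prune"):
            raise ValidationError("align_policy must be 'strict' or 'prune'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dominance_thresholds" in raw:
            raw["dominance_thresholds"] = tuple(raw["dominance_thresholds"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Derive a reproducible per-stage seed from the master seed.

        Keeps each stage independently re-runnable: the stream a stage sees
        depends only on (master seed, stage name).
        """
        ss = np.random.SeedSequence([self.seed, int.from_bytes(stage.encode(), "big") % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31))
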