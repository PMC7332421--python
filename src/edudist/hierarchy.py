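"""Location hierarchy: country -> region -> super-region.

Used for nested random effects, spatial distance tiers in the ensemble stage,
and population-weighted aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: spatial distance tiers used by the ensemble weighting stage
LOC_DIST_SAME_COUNTRY = 0.001
LOC_DIST_SAME_REGION = 0.33
LOC_DIST_SAME_SUPER_REGION = 0.66
LOC_DIST_OTHER = 1.0


@dataclass(frozen=True)
class Hierarchy:
    """Immutable country -> region -> super-region tree.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``location_id``, ``region``, ``super_region``; one row per
        country.
    """

    table: pd.DataFrame
    _region: dict = field(init=False, repr=False)
    _super: dict = field(init=False, repr=False)

    def __post_init__(self):
        t = self.table
        for col in ("location_id", "region", "super_region"):
            if col not in t.columns:
                raise ValueError(f"hierarchy table missing column {col!r}")
        if t["location_id"].duplicated().any():
            raise ValueError("duplicate location_id in hierarchy table")
        object.__setattr__(self, "_region", dict(zip(t["location_id"], t["region"])))
        object.__setattr__(self, "_super", dict(zip(t["location_id"], t["super_region"])))

    @property
    def countries(self) -> list:
        return list(self.table["location_id"])

    @property
    def regions(self) -> list:
        return sorted(self.table["region"].unique())

    @property
    def super_regions(self) -> list:
        return sorted(self.table["super_region"].unique())

    def region_of(self, location) -> str:
        try:
            return self._region[location]
        except KeyError:
            raise KeyError(f"unknown location {location!r}") from None

    def super_region_of(self, location) -> str:
        try:
            return self._super[location]
        except KeyError:
            raise KeyError(f"unknown location {location!r}") from None

    def countries_in_region(self, region) -> list:
        return list(self.table.loc[self.table["region"] == region, "location_id"])

    def location_distance(self, a, b) -> float:
        """Tiered spatial distance between two countries."""
        if a == b:
            return LOC_DIST_SAME_COUNTRY
        if self.region_of(a) == self.region_of(b):
            return LOC_DIST_SAME_REGION
        if self.super_region_of(a) == self.super_region_of(b):
            return LOC_DIST_SAME_SUPER_REGION
        return LOC_DIST_OTHER

    def attach(self, df: pd.DataFrame, location_col: str = "location_id") -> pd.DataFrame:
        """Return ``df`` with ``region`` and ``super_region`` columns merged on."""
        out = df.copy()
        out["region"] = out[location_col].map(self._region)
        out["super_region"] = out[location_col].map(self._super)
        if out["region"].isna().any():
            bad = sorted(out.loc[out["region"].isna(), location_col].unique())
            raise KeyError(f"locations not in hierarchy: {bad}")
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hierarchy":
        return cls(pd.read_csv(path))
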