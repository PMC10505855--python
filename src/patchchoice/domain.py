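"""Domain types and tabular I/O for Inuit foraging-trip analyses.

The unit of analysis is a foraging episode ("trip"): one harvester, one
patch (a season/habitat/method category of foraging activity), a binary
harvest-success outcome, and household-level socio-economic covariates
(income and position in the community food-sharing network).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "PatchCatalog",
    "TripRecord",
    "TripTable",
    "HouseholdTable",
    "CovariateScaling",
    "SampleSummary",
    "read_trip_table",
    "write_trip_table",
    "read_household_table",
    "write_household_table",
    "standardize_covariates",
    "compute_network_degrees",
    "summarize_sample",
    "SEASONS",
    "GENDERS",
    "AGE_CLASSES",
]

SEASONS = ("ice", "ice_free")
GENDERS = ("man", "woman")
AGE_CLASSES = ("under30", "30to40", "40to50", "over50")

#: Covariates that enter the regression models on a standardized scale.
STANDARDIZED_COVARIATES = ("income", "in_degree", "out_degree", "group_size")

TRIP_COLUMNS = [
    "trip_id",
    "harvester_id",
    "household_id",
    "gender",
    "age_class",
    "season",
    "patch",
    "success",
    "group_size",
    "income",
    "in_degree",
    "out_degree",
]


class DomainError(ValueError):
    """Raised when input data violate a domain invariant."""


# ---------------------------------------------------------------------------
# Patch taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    """One foraging-patch category: a season/habitat/method class of activity."""

    name: str
    season_tag: str  # "ice", "ice_free", or "both"
    major_resources: str = ""
    major_methods: str = ""

    def __post_init__(self) -> None:
        if self.season_tag not in ("ice", "ice_free", "both"):
            raise DomainError(f"invalid season_tag {self.season_tag!r} for patch {self.name!r}")


def _squash(label: str) -> str:
    """Canonical comparison key for a patch label: lowercase alphanumerics only."""
    return re.sub(r"[^a-z0-9]", "", label.lower())


@dataclass(frozen=True)
class PatchCatalog:
    """Ordered collection of foraging-patch categories.

    The default catalog holds the seven patches used throughout: three
    ice-season patches (winter inland, winter marine, spring inland), two
    ice-free patches (summer/autumn inland and marine), and two that are
    pursued year-round (tidal gathering, incidental harvests embedded in
    other travel).
    """

    patches: tuple[Patch, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.patches]
        if not names:
            raise DomainError("catalog must contain at least one patch")
        if len(set(names)) != len(names):
            raise DomainError("patch identifiers must be unique")

    @staticmethod
    def default() -> "PatchCatalog":
        cat = PatchCatalog(
            patches=(
                Patch("winter_inland", "ice", "char", "ice netting, rifle snowmobile hunting"),
                Patch("winter_marine", "ice", "seal, polar bear", "rifle hunting at ice floe edge"),
                Patch("spring_inland", "ice", "char, goose, ptarmigan", "ice jigging, rifle snowmobile hunting"),
                Patch("summerautumn_inland", "ice_free", "caribou, char", "rifle ATV hunting, lake rod and net fishing"),
                Patch("summerautumn_marine", "ice_free", "beluga, seal, char", "canoe hunting, netting, rod fishing"),
                Patch("tidal", "both", "mussels", "gathering at low tide"),
                Patch("incidental", "both", "char, birds", "embedded in other activities on the land"),
            )
        )
        assert len(cat.patches) == 7
        return cat

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.patches)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self) -> Iterator[Patch]:
        return iter(self.patches)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def season_tag(self, name: str) -> str:
        return self.patches[self.index(name)].season_tag

    def resolve(self, label: str) -> str:
        """Map a raw patch label (any case/punctuation) to its canonical name.

        ``"Winter Marine"`` and ``"summer/autumn marine"`` resolve to
        ``winter_marine`` and ``summerautumn_marine``.  Raises
        :class:`DomainError` for labels not in the catalog.
        """
        key = _squash(label)
        for p in self.patches:
            if _squash(p.name) == key:
                return p.name
        raise DomainError(f"unknown patch label {label!r}")

    def season_compatible(self, patch: str, season: str) -> bool:
        tag = self.season_tag(patch)
        return tag == "both" or tag == season


# ---------------------------------------------------------------------------
# Trip records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripRecord:
    """One foraging episode with its covariates."""

    trip_id: str
    harvester_id: str
    household_id: str
    gender: str
    age_class: str
    season: str
    patch: str
    success: int
    group_size: int
    income: float  # raw household income; NaN encodes missing
    in_degree: int
    out_degree: int
    # standardized covariates, populated by standardize_covariates
    income_std: float = float("nan")
    in_degree_std: float = float("nan")
    out_degree_std: float = float("nan")
    group_size_std: float = float("nan")


class TripTable:
    """Validated table of foraging trips, backed by a pandas DataFrame.

    ``income`` uses NaN for explicitly-missing household income; standardized
    columns (``*_std``) exist only after :func:`standardize_covariates`.
    """

    def __init__(self, df: pd.DataFrame, catalog: PatchCatalog, *, validate: bool = True,
                 strict_season: bool = True):
        self.catalog = catalog
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate(strict_season=strict_season)

    def _validate(self, strict_season: bool) -> None:
        df = self.df
        missing_cols = [c for c in TRIP_COLUMNS if c not in df.columns]
        if missing_cols:
            raise DomainError(f"trip table missing columns: {missing_cols}")
        if df["trip_id"].duplicated().any():
            dup = df.loc[df["trip_id"].duplicated(), "trip_id"].iloc[0]
            raise DomainError(f"duplicate trip_id {dup!r}")
        for i, row in df.iterrows():
            rowno = i + 1
            if row["gender"] not in GENDERS:
                raise DomainError(f"row {rowno}: invalid gender {row['gender']!r}")
            if row["age_class"] not in AGE_CLASSES:
                raise DomainError(f"row {rowno}: invalid age_class {row['age_class']!r}")
            if row["season"] not in SEASONS:
                raise DomainError(f"row {rowno}: invalid season {row['season']!r}")
            if row["patch"] not in self.catalog.names:
                raise DomainError(f"row {rowno}: unknown patch label {row['patch']!r}")
            if int(row["group_size"]) < 1:
                raise DomainError(f"row {rowno}: group_size must be >= 1, got {row['group_size']}")
            if int(row["in_degree"]) < 0 or int(row["out_degree"]) < 0:
                raise DomainError(f"row {rowno}: negative network degree")
            if int(row["success"]) not in (0, 1):
                raise DomainError(f"row {rowno}: success must be 0/1")
            if strict_season and not self.catalog.season_compatible(row["patch"], row["season"]):
                raise DomainError(
                    f"row {rowno}: patch {row['patch']!r} incompatible with season {row['season']!r}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[TripRecord]:
        std = self.is_standardized
        for _, row in self.df.iterrows():
            yield TripRecord(
                trip_id=str(row["trip_id"]),
                harvester_id=str(row["harvester_id"]),
                household_id=str(row["household_id"]),
                gender=row["gender"],
                age_class=row["age_class"],
                season=row["season"],
                patch=row["patch"],
                success=int(row["success"]),
                group_size=int(row["group_size"]),
                income=float(row["income"]) if pd.notna(row["income"]) else float("nan"),
                in_degree=int(row["in_degree"]),
                out_degree=int(row["out_degree"]),
                income_std=float(row["income_std"]) if std and pd.notna(row["income_std"]) else float("nan"),
                in_degree_std=float(row["in_degree_std"]) if std else float("nan"),
                out_degree_std=float(row["out_degree_std"]) if std else float("nan"),
                group_size_std=float(row["group_size_std"]) if std else float("nan"),
            )

    @property
    def is_standardized(self) -> bool:
        return "income_std" in self.df.columns

    def copy(self) -> "TripTable":
        return TripTable(self.df.copy(), self.catalog, validate=False)


# ---------------------------------------------------------------------------
# Households
# ---------------------------------------------------------------------------

@dataclass
class HouseholdTable:
    """Per-household income (NaN = missing) and food-sharing-network degrees."""

    df: pd.DataFrame  # columns: household_id, income, in_degree, out_degree, n_hunters

    COLUMNS = ["household_id", "income", "in_degree", "out_degree", "n_hunters"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise DomainError(f"household table missing columns: {missing}")
        if self.df["household_id"].duplicated().any():
            raise DomainError("duplicate household_id")
        if (self.df[["in_degree", "out_degree", "n_hunters"]] < 0).any().any():
            raise DomainError("negative degree or hunter count")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def missing_income_ids(self) -> list[str]:
        return list(self.df.loc[self.df["income"].isna(), "household_id"])


# ---------------------------------------------------------------------------
# Covariate standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateScaling:
    """Centre/scale pairs used to standardize model covariates.

    Scales use the sample standard deviation (n-1 denominator).  Observed raw
    ranges are kept so counterfactual predictions can refuse to extrapolate
    beyond the data (income sweeps are clamped to ``income_range``).
    """

    means: dict[str, float]
    sds: dict[str, float]
    standardized: tuple[str, ...] = STANDARDIZED_COVARIATES
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise DomainError(f"scale for {name!r} must be strictly positive")

    def transform(self, name: str, value):
        return (np.asarray(value, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, value):
        return np.asarray(value, dtype=float) * self.sds[name] + self.means[name]

    @property
    def income_range(self) -> tuple[float, float]:
        return self.ranges["income"]


def standardize_covariates(trips: TripTable) -> tuple[TripTable, CovariateScaling]:
    """Centre and scale income, network degrees and group size.

    Means/sds are computed over non-missing entries; missing income stays
    missing (NaN) in the standardized column.  Raises on constant covariates.
    """
    df = trips.df.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name in STANDARDIZED_COVARIATES:
        vals = pd.to_numeric(df[name], errors="coerce")
        obs = vals.dropna()
        if obs.nunique() < 2:
            raise DomainError(f"covariate {name!r} has fewer than 2 distinct observed values")
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        if sd == 0:
            raise DomainError(f"covariate {name!r} is constant (sd = 0)")
        means[name] = mu
        sds[name] = sd
        ranges[name] = (float(obs.min()), float(obs.max()))
        df[f"{name}_std"] = (vals - mu) / sd
    scaling = CovariateScaling(means=means, sds=sds, ranges=ranges)
    return TripTable(df, trips.catalog, validate=False), scaling


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_trip_table(path, catalog: PatchCatalog, *, strict_season: bool = True) -> TripTable:
    """Read a trip CSV, resolving patch labels case-insensitively.

    Missing income must be an empty field; sentinel numbers are not
    interpreted.  Any invariant violation is reported with its row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"trip_id": str, "harvester_id": str, "household_id": str})
    extra = [c for c in df.columns if c not in TRIP_COLUMNS]
    if extra:
        raise DomainError(f"unexpected columns in {path.name}: {extra}")
    resolved = []
    for i, label in enumerate(df["patch"]):
        try:
            resolved.append(catalog.resolve(str(label)))
        except DomainError as exc:
            raise DomainError(f"row {i + 1}: {exc}") from None
    df["patch"] = resolved
    df["income"] = pd.to_numeric(df["income"], errors="coerce")
    for col in ("success", "group_size", "in_degree", "out_degree"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return TripTable(df, catalog, strict_season=strict_season)


def write_trip_table(trips: TripTable, path) -> None:
    """Write the raw trip columns to CSV (missing income as empty field)."""
    trips.df[TRIP_COLUMNS].to_csv(path, index=False)


def read_household_table(path) -> HouseholdTable:
    df = pd.read_csv(path, dtype={"household_id": str})
    df["income"] = pd.to_numeric(df["income"], errors="coerce")
    for col in ("in_degree", "out_degree", "n_hunters"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return HouseholdTable(df)


def write_household_table(households: HouseholdTable, path) -> None:
    households.df[HouseholdTable.COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Food-sharing network degrees
# ---------------------------------------------------------------------------

def compute_network_degrees(
    edges: Iterable[tuple[str, str, str]],
    households: Sequence[str],
) -> pd.DataFrame:
    """Directed sharing-network degrees, excluding each household's own reports.

    ``edges`` are ``(giver, receiver, reporter)`` household triples from
    sharing surveys.  A household h's in-degree counts distinct households
    reported as giving to h by reporters other than h; its out-degree counts
    distinct households reported as receiving from h by reporters other than
    h.  Self-loops are dropped.  Duplicate reports of the same tie count once.
    """
    households = list(households)
    hh_set = set(households)
    givers: dict[str, set[str]] = {h: set() for h in households}
    receivers: dict[str, set[str]] = {h: set() for h in households}
    for giver, receiver, reporter in edges:
        if giver not in hh_set or receiver not in hh_set:
            raise DomainError(f"edge references unknown household: {giver!r} -> {receiver!r}")
        if giver == receiver:
            continue
        if reporter != receiver:
            givers[receiver].add(giver)
        if reporter != giver:
            receivers[giver].add(receiver)
    return pd.DataFrame(
        {
            "household_id": households,
            "in_degree": [len(givers[h]) for h in households],
            "out_degree": [len(receivers[h]) for h in households],
        }
    )


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

@dataclass
class SampleSummary:
    """Descriptive statistics of a trip table.

    Quantiles use linear interpolation between order statistics.  Income
    correlations are Pearson, over households with non-missing income.
    """

    n_trips: int
    trips_per_patch: dict[str, int]
    trips_per_gender: dict[str, int]
    trips_per_harvester_quantiles: tuple[float, float, float]  # 25/50/75%
    group_size_quantiles: tuple[float, float, float]
    corr_income_in_degree: float
    corr_income_out_degree: float
    corr_in_out_degree: float
    n_households_income_known: int

    def as_dict(self) -> dict:
        return {
            "n_trips": self.n_trips,
            "trips_per_patch": self.trips_per_patch,
            "trips_per_gender": self.trips_per_gender,
            "trips_per_harvester_quantiles": list(self.trips_per_harvester_quantiles),
            "group_size_quantiles": list(self.group_size_quantiles),
            "corr_income_in_degree": self.corr_income_in_degree,
            "corr_income_out_degree": self.corr_income_out_degree,
            "corr_in_out_degree": self.corr_in_out_degree,
            "n_households_income_known": self.n_households_income_known,
        }


def summarize_sample(trips: TripTable, households: HouseholdTable) -> SampleSummary:
    if len(trips) == 0:
        raise DomainError("cannot summarize an empty trip table")
    df = trips.df
    per_patch = {p: int((df["patch"] == p).sum()) for p in trips.catalog.names}
    per_gender = {g: int((df["gender"] == g).sum()) for g in GENDERS}
    per_harv = df.groupby("harvester_id").size().to_numpy(dtype=float)
    harv_q = tuple(np.quantile(per_harv, [0.25, 0.5, 0.75]))
    gs_q = tuple(np.quantile(df["group_size"].to_numpy(dtype=float), [0.25, 0.5, 0.75]))

    hh = households.df
    known = hh.dropna(subset=["income"])
    corr_inc_in = float(known["income"].corr(known["in_degree"]))
    corr_inc_out = float(known["income"].corr(known["out_degree"]))
    corr_in_out = float(hh["in_degree"].corr(hh["out_degree"]))
    return SampleSummary(
        n_trips=len(df),
        trips_per_patch=per_patch,
        trips_per_gender=per_gender,
        trips_per_harvester_quantiles=harv_q,
        group_size_quantiles=gs_q,
        corr_income_in_degree=corr_inc_in,
        corr_income_out_degree=corr_inc_out,
        corr_in_out_degree=corr_in_out,
        n_households_income_known=len(known),
    )
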