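"""Synthetic foraging-trip data.

The study's field data are confidential, so this module provides two kinds
of stand-ins:

* a deterministic margin-matched fixture reproducing the published sample
  composition — 281 trips by 23 harvesters in 13 households, the per-patch
  trip counts, the men/women trip split, group-size quartiles (2, 3, 4),
  one household with missing income covering 35 trips by 3 hunters, and the
  published correlation structure among household income and sharing-network
  degrees; and
* a model-based simulator drawing trips from the generative patch-choice and
  harvest-success model at known true parameters, for recovery tests.

Harvester-level composition (how many of the 23 harvesters are women, their
age classes, per-harvester trip counts) is not published; the fixture's
choices there are documented assumptions, not reproduced facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .domain import (
    AGE_CLASSES,
    GENDERS,
    TRIP_COLUMNS,
    CovariateScaling,
    DomainError,
    HouseholdTable,
    PatchCatalog,
    TripTable,
    standardize_covariates,
)
from .model import (
    ModelLayout,
    ModelParams,
    TripDesign,
    choice_linpred_matrix,
    softmax_probs,
    success_linpred,
)

__all__ = [
    "GeneratorConfig",
    "TrueParams",
    "SimulationDesign",
    "solve_household_table",
    "default_fixture",
    "simulate_trips",
    "inject_missing_income",
]

DEFAULT_PATCH_MARGINS = {
    "winter_inland": 47,
    "winter_marine": 38,
    "spring_inland": 72,
    "summerautumn_inland": 21,
    "summerautumn_marine": 75,
    "tidal": 20,
    "incidental": 8,
}

#: Group-size multiset for the fixture: 281 integers whose 25/50/75% quantiles
#: (linear interpolation) are exactly (2, 3, 4).
_GROUP_SIZE_COUNTS = {1: 40, 2: 60, 3: 60, 4: 70, 5: 30, 6: 15, 8: 6}


@dataclass
class GeneratorConfig:
    """Targets the fixture must hit; defaults are the published margins."""

    n_trips: int = 281
    n_harvesters: int = 23
    n_households: int = 13
    patch_margins: dict = field(default_factory=lambda: dict(DEFAULT_PATCH_MARGINS))
    men_trips: int = 228
    missing_income_household: bool = True
    missing_household_hunters: int = 3
    missing_household_trips: int = 35
    corr_income_in_degree: float = -0.22
    corr_income_out_degree: float = 0.39
    corr_in_out_degree: float = -0.07
    corr_tolerance: float = 0.005
    group_size_quartiles: tuple = (2, 3, 4)
    seed: int = 20230395

    def validate(self) -> None:
        if sum(self.patch_margins.values()) != self.n_trips:
            raise DomainError(
                f"patch margins sum to {sum(self.patch_margins.values())}, expected {self.n_trips}"
            )
        if self.men_trips > self.n_trips:
            raise DomainError("men_trips cannot exceed n_trips")
        for c in (self.corr_income_in_degree, self.corr_income_out_degree, self.corr_in_out_degree):
            if not abs(c) < 1:
                raise DomainError("target correlations must satisfy |r| < 1")


# ---------------------------------------------------------------------------
# Ground-truth parameters
# ---------------------------------------------------------------------------

#: Baseline per-patch success probabilities used by the fixture and the
#: default simulator.  Winter marine hunting is the canonical low-yield
#: activity (roughly a fifth to a quarter of trips succeed); tidal gathering
#: is nearly always successful.
DEFAULT_SUCCESS_BASELINE = {
    "winter_inland": 0.70,
    "winter_marine": 0.225,
    "spring_inland": 0.80,
    "summerautumn_inland": 0.60,
    "summerautumn_marine": 0.50,
    "tidal": 0.95,
    "incidental": 0.75,
}


@dataclass
class TrueParams:
    """Generative ground truth: full model parameters + success baselines."""

    params: ModelParams
    success_baseline: dict

    def __post_init__(self) -> None:
        for patch, p in self.success_baseline.items():
            if not 0 < p < 1:
                raise DomainError(f"baseline success probability for {patch!r} not in (0,1)")

    @staticmethod
    def default(catalog: Optional[PatchCatalog] = None) -> "TrueParams":
        """Moderate, field-plausible effects around the published margins.

        Choice intercepts track the observed patch shares with a season
        offset discouraging out-of-season patches; income pushes choice
        away from winter marine and toward inland patches, and has no effect
        on success (the published finding).
        """
        cat = catalog or PatchCatalog.default()
        layout = ModelLayout.default(cat)
        p = ModelParams.zeros(layout)
        shares = np.array([DEFAULT_PATCH_MARGINS[k] for k in cat.names], dtype=float)
        base = np.log(shares / shares.sum())
        for k, patch in enumerate(cat.patches):
            for s, season in enumerate(layout.seasons):
                off = 0.0 if patch.season_tag in ("both", season) else -4.0
                p.alpha_choice[k, s] = base[k] + off
        cov = layout.choice_covariates
        inc = cov.index("income_std")
        p.beta_choice[cat.index("winter_marine"), inc] = -0.6
        p.beta_choice[cat.index("winter_inland"), inc] = 0.4
        p.beta_choice[cat.index("summerautumn_inland"), inc] = 0.3
        p.beta_choice[cat.index("spring_inland"), inc] = 0.2
        p.beta_choice[cat.index("winter_marine"), cov.index("in_degree_std")] = -0.3
        p.beta_choice[cat.index("spring_inland"), cov.index("group_size_std")] = 0.4
        p.gamma_choice[cat.index("winter_marine"), layout.genders.index("woman")] = -1.5
        p.gamma_choice[cat.index("tidal"), layout.genders.index("woman")] = 0.8
        p.age_effect_choice[:] = 0.0
        p.gp_choice = np.array([0.5, 0.3, 0.1])
        for k, patch in enumerate(cat.names):
            p.alpha_succ[k, :] = logit(DEFAULT_SUCCESS_BASELINE[patch])
        p.beta_succ[:] = 0.0  # income (and the rest) do not move success
        p.beta_succ[cov.index("group_size_std")] = 0.1
        p.gamma_succ[:] = 0.0
        p.age_effect_succ[:] = 0.0
        p.gp_succ = np.array([0.5, 0.3, 0.1])
        return TrueParams(params=p, success_baseline=dict(DEFAULT_SUCCESS_BASELINE))


# ---------------------------------------------------------------------------
# Household table with target correlations
# ---------------------------------------------------------------------------

def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def solve_household_table(config: Optional[GeneratorConfig] = None) -> HouseholdTable:
    """Deterministic 13-household table matching the published correlations.

    Degrees are found by seeded local search over nonnegative integers with
    mean near 4 (the reference tie count used in the counterfactual
    profiles) until corr(in, out) hits its target; incomes for the 12
    income-known households are then tuned by coordinate descent against the
    income-degree correlations.  The missing-income household keeps income
    NaN and 3 hunters.
    """
    config = config or GeneratorConfig()
    config.validate()
    n = config.n_households
    if n < 3:
        raise DomainError("household correlations are underdetermined with fewer than 3 households")
    rng = np.random.default_rng(config.seed)
    tol = config.corr_tolerance * 0.6  # solve tighter than we promise

    # -- integer degrees: local search on corr(in, out) over all n households
    def degree_search() -> tuple[np.ndarray, np.ndarray]:
        best_in = np.clip(rng.poisson(4.0, size=n), 0, 10)
        best_out = np.clip(rng.poisson(4.0, size=n), 0, 10)
        # guard against degenerate starts
        for v in (best_in, best_out):
            if len(np.unique(v)) < 2:
                v[0] += 2
        err = abs(_corr(best_in, best_out) - config.corr_in_out_degree)
        for _ in range(20000):
            if err <= tol:
                break
            which = rng.integers(2)
            vec = best_in if which == 0 else best_out
            i = rng.integers(n)
            delta = rng.choice([-1, 1])
            new = vec.copy()
            new[i] = np.clip(new[i] + delta, 0, 10)
            mean = new.mean()
            if not (3.0 <= mean <= 5.0) or len(np.unique(new)) < 2:
                continue
            cand_in, cand_out = (new, best_out) if which == 0 else (best_in, new)
            cand_err = abs(_corr(cand_in, cand_out) - config.corr_in_out_degree)
            if cand_err < err:
                best_in, best_out, err = cand_in, cand_out, cand_err
        return best_in, best_out, err

    in_deg, out_deg, deg_err = degree_search()

    # -- incomes for the 12 known households: coordinate descent on two corrs
    miss_idx = n // 2  # mid-table household carries the missing income
    known = np.array([i for i in range(n) if i != miss_idx])
    inc = rng.uniform(30.0, 110.0, size=len(known))  # arbitrary currency units (thousands)
    t_in, t_out = config.corr_income_in_degree, config.corr_income_out_degree

    def income_err(v: np.ndarray) -> float:
        return max(
            abs(_corr(v, in_deg[known]) - t_in),
            abs(_corr(v, out_deg[known]) - t_out),
        )

    err = income_err(inc)
    step = 20.0
    for _ in range(200):
        improved = False
        for i in range(len(inc)):
            for delta in (step, -step):
                cand = inc.copy()
                cand[i] = max(5.0, cand[i] + delta)
                e = income_err(cand)
                if e < err:
                    inc, err = cand, e
                    improved = True
        if err <= tol:
            break
        if not improved:
            step *= 0.5
            if step < 1e-6:
                break

    achieved = {
        "corr_in_out": _corr(in_deg, out_deg),
        "corr_income_in": _corr(inc, in_deg[known]),
        "corr_income_out": _corr(inc, out_deg[known]),
    }
    if deg_err > config.corr_tolerance or err > config.corr_tolerance:
        raise DomainError(f"household solver missed correlation targets; best achieved: {achieved}")

    income = np.full(n, np.nan)
    income[known] = inc
    # 23 hunters over 13 households; the missing-income household has 3.
    hunters = np.ones(n, dtype=int)
    hunters[miss_idx] = config.missing_household_hunters
    spare = config.n_harvesters - hunters.sum()
    order = [i for i in range(n) if i != miss_idx]
    j = 0
    while spare > 0:
        hunters[order[j % len(order)]] += 1
        spare -= 1
        j += 1
    df = pd.DataFrame(
        {
            "household_id": [f"H{i + 1:02d}" for i in range(n)],
            "income": income,
            "in_degree": in_deg,
            "out_degree": out_deg,
            "n_hunters": hunters,
        }
    )
    if not config.missing_income_household:
        df.loc[miss_idx, "income"] = float(np.median(inc))
    return HouseholdTable(df)


# ---------------------------------------------------------------------------
# Margin-matched fixture
# ---------------------------------------------------------------------------

def _harvester_roster(config: GeneratorConfig, households: HouseholdTable) -> pd.DataFrame:
    """23 harvesters with genders, age classes and per-harvester trip counts.

    18 men / 5 women (an assumption; only the trip-level split of 228/53 is
    published).  The missing-income household's 3 hunters are men and carry
    exactly 35 trips between them.
    """
    hh = households.df
    miss_ids = households.missing_income_ids
    miss_id = miss_ids[0] if miss_ids else None

    rows = []
    # women's trip counts: 53 trips over 5 harvesters
    women_counts = [20, 14, 9, 6, 4]
    # missing household: 3 men, 35 trips
    miss_counts = [18, 12, 5]
    # remaining 15 men: 193 trips
    men_counts = [60, 30, 22, 18, 14, 12, 10, 8, 6, 4, 3, 2, 2, 1, 1]
    assert sum(women_counts) + sum(miss_counts) + sum(men_counts) == config.n_trips
    assert sum(miss_counts) + sum(men_counts) == config.men_trips

    # household slots: each household hosts n_hunters harvesters
    slots = []
    for _, r in hh.iterrows():
        slots.extend([r["household_id"]] * int(r["n_hunters"]))
    non_miss_slots = [h for h in slots if h != miss_id]

    hid = 1
    ages = list(AGE_CLASSES)
    for j, c in enumerate(miss_counts):
        rows.append(("X%02d" % hid, miss_id, "man", ages[j % 4], c))
        hid += 1
    for j, c in enumerate(men_counts):
        rows.append(("X%02d" % hid, non_miss_slots[j], "man", ages[(j + 1) % 4], c))
        hid += 1
    for j, c in enumerate(women_counts):
        rows.append(("X%02d" % hid, non_miss_slots[len(men_counts) + j], "woman", ages[j % 4], c))
        hid += 1
    return pd.DataFrame(rows, columns=["harvester_id", "household_id", "gender", "age_class", "n_trips"])


def default_fixture(
    config: Optional[GeneratorConfig] = None,
    true_params: Optional[TrueParams] = None,
    catalog: Optional[PatchCatalog] = None,
) -> tuple[TripTable, HouseholdTable]:
    """Deterministic fixture matching every published margin exactly.

    Counts (patch margins, gender split, missing-household trips, group-size
    quartiles) are satisfied by construction — lists are laid out exactly and
    then shuffled with the seed — so they hold for every seed; only success
    flags and season assignment of year-round patches are sampled.
    """
    config = config or GeneratorConfig()
    config.validate()
    cat = catalog or PatchCatalog.default()
    tp = true_params or TrueParams.default(cat)
    rng = np.random.default_rng(config.seed)

    households = solve_household_table(config)
    roster = _harvester_roster(config, households)
    miss_ids = households.missing_income_ids
    miss_id = miss_ids[0] if miss_ids else None

    # expand exact lists, then shuffle
    patches = [p for p, c in config.patch_margins.items() for _ in range(c)]
    harvesters = [r["harvester_id"] for _, r in roster.iterrows() for _ in range(int(r["n_trips"]))]
    group_sizes = [g for g, c in _GROUP_SIZE_COUNTS.items() for _ in range(c)]
    if len(group_sizes) != config.n_trips:
        # non-default n_trips: fall back to sampling sizes around the quartiles
        q1, q2, q3 = config.group_size_quartiles
        group_sizes = list(rng.choice([q1, q2, q3], size=config.n_trips))
    rng.shuffle(patches)
    rng.shuffle(harvesters)
    rng.shuffle(group_sizes)

    hinfo = roster.set_index("harvester_id")
    hh = households.df.set_index("household_id")

    # women are never observed in the winter marine patch: swap those slots
    # with a man's non-winter-marine trip (preserves both margins)
    for i in range(config.n_trips):
        if patches[i] == "winter_marine" and hinfo.loc[harvesters[i], "gender"] == "woman":
            for j in range(config.n_trips):
                if patches[j] != "winter_marine" and hinfo.loc[harvesters[j], "gender"] == "man":
                    patches[i], patches[j] = patches[j], patches[i]
                    break

    seasons = []
    for p in patches:
        tag = cat.season_tag(p)
        seasons.append(tag if tag != "both" else ("ice" if rng.random() < 0.5 else "ice_free"))

    rows = []
    for i in range(config.n_trips):
        h = harvesters[i]
        hhid = hinfo.loc[h, "household_id"]
        income = hh.loc[hhid, "income"]
        rows.append(
            {
                "trip_id": f"T{i + 1:03d}",
                "harvester_id": h,
                "household_id": hhid,
                "gender": hinfo.loc[h, "gender"],
                "age_class": hinfo.loc[h, "age_class"],
                "season": seasons[i],
                "patch": patches[i],
                "success": 0,
                "group_size": int(group_sizes[i]),
                "income": income,
                "in_degree": int(hh.loc[hhid, "in_degree"]),
                "out_degree": int(hh.loc[hhid, "out_degree"]),
            }
        )
    df = pd.DataFrame(rows, columns=TRIP_COLUMNS)

    # success flags from the true success model; the missing household's
    # latent income is proxied by the median observed income for generation
    gen = df.copy()
    gen["income"] = gen["income"].fillna(hh["income"].median())
    gen_trips, _ = standardize_covariates(TripTable(gen, cat, validate=False))
    from .model import build_design  # local import to avoid cycle at module load

    design = build_design(gen_trips, tp.params.layout)
    p_succ = expit(success_linpred(design, tp.params))
    df["success"] = (rng.random(config.n_trips) < p_succ).astype(int)

    trips = TripTable(df, cat, strict_season=True)
    return trips, households


# ---------------------------------------------------------------------------
# Model-based simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """Covariate layout for model-based simulation.

    ``harvesters`` carries one row per harvester (id, household, gender, age
    class); ``households`` supplies income and degrees; seasons and group
    sizes are drawn from the given distributions.  Covariates are
    standardized internally against the design's own raw values.
    """

    harvesters: pd.DataFrame
    households: HouseholdTable
    catalog: PatchCatalog
    season_ice_prob: float = 0.5
    group_size_values: tuple = (1, 2, 3, 4, 5, 6, 8)
    group_size_probs: tuple = (0.14, 0.21, 0.21, 0.25, 0.11, 0.06, 0.02)

    @staticmethod
    def from_fixture(config: Optional[GeneratorConfig] = None) -> "SimulationDesign":
        config = config or GeneratorConfig()
        households = solve_household_table(config)
        roster = _harvester_roster(config, households)
        hh = households.df.copy()
        hh["income"] = hh["income"].fillna(hh["income"].median())
        return SimulationDesign(
            harvesters=roster[["harvester_id", "household_id", "gender", "age_class"]],
            households=HouseholdTable(hh),
            catalog=PatchCatalog.default(),
        )


def simulate_trips(
    true_params: TrueParams,
    design: SimulationDesign,
    n: int,
    seed: int,
) -> TripTable:
    """Draw n trips from the generative model at the given true parameters.

    For each trip a harvester, season and group size are drawn from the
    design; the patch is drawn from the softmax choice model at the trip's
    covariates and success from the logistic success model given that patch.
    Season consistency is not enforced (the season enters only through the
    intercepts), so the resulting table is validated in non-strict mode.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    params = true_params.params
    layout = params.layout
    cat = design.catalog
    rng = np.random.default_rng(seed)

    harv = design.harvesters.reset_index(drop=True)
    hh = design.households.df.set_index("household_id")
    hidx = rng.integers(len(harv), size=n)
    season = np.where(rng.random(n) < design.season_ice_prob, "ice", "ice_free")
    gsize = rng.choice(design.group_size_values, size=n, p=np.asarray(design.group_size_probs))

    hhid = harv["household_id"].to_numpy()[hidx]
    income = hh.loc[hhid, "income"].to_numpy(dtype=float)
    in_deg = hh.loc[hhid, "in_degree"].to_numpy(dtype=float)
    out_deg = hh.loc[hhid, "out_degree"].to_numpy(dtype=float)

    def std(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    covs = {
        "income_std": std(income),
        "in_degree_std": std(in_deg),
        "out_degree_std": std(out_deg),
        "group_size_std": std(gsize.astype(float)),
    }
    Xc = np.column_stack([covs[c] for c in layout.choice_covariates]) if layout.choice_covariates else np.zeros((n, 0))
    Xs = np.column_stack([covs[c] for c in layout.success_covariates]) if layout.success_covariates else np.zeros((n, 0))

    tdesign = TripDesign(
        layout=layout,
        patch_idx=np.zeros(n, dtype=int),  # filled after the choice draw
        season_idx=np.array([layout.seasons.index(s) for s in season]),
        gender_idx=np.array([layout.genders.index(g) for g in harv["gender"].to_numpy()[hidx]])
        if layout.has_gender
        else np.zeros(n, int),
        age_idx=np.array([layout.age_classes.index(a) for a in harv["age_class"].to_numpy()[hidx]])
        if layout.has_age
        else np.zeros(n, int),
        Xc=Xc,
        Xs=Xs,
        y=np.zeros(n),
        missing_income=np.zeros(n, dtype=bool),
    )
    probs = softmax_probs(choice_linpred_matrix(tdesign, params))
    u = rng.random(n)
    patch_idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    tdesign.patch_idx = patch_idx
    p_succ = expit(success_linpred(tdesign, params))
    success = (rng.random(n) < p_succ).astype(int)

    df = pd.DataFrame(
        {
            "trip_id": [f"S{i + 1:06d}" for i in range(n)],
            "harvester_id": harv["harvester_id"].to_numpy()[hidx],
            "household_id": hhid,
            "gender": harv["gender"].to_numpy()[hidx],
            "age_class": harv["age_class"].to_numpy()[hidx],
            "season": season,
            "patch": [layout.patches[k] for k in patch_idx],
            "success": success,
            "group_size": gsize.astype(int),
            "income": income,
            "in_degree": in_deg.astype(int),
            "out_degree": out_deg.astype(int),
        }
    )
    return TripTable(df, cat, strict_season=False)


def inject_missing_income(trips: TripTable, household_id: str) -> TripTable:
    """Set income to missing (NaN) for every trip of one household."""
    if household_id not in set(trips.df["household_id"]):
        raise DomainError(f"unknown household {household_id!r}")
    df = trips.df.copy()
    sel = df["household_id"] == household_id
    df.loc[sel, "income"] = np.nan
    if "income_std" in df.columns:
        df.loc[sel, "income_std"] = np.nan
    return TripTable(df, trips.catalog, validate=False)
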