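"""Response series: size-at-age, length-specific growth, differences.

Turns back-calculated trajectories into the annual response series the
BACIPS analysis operates on:

* size-at-age k: mean back-calculated length at age k per area and
  calendar year (year = birth_year + k);
* length-specific growth G_L = (L_{t+1} - L_t) / L_t within discrete,
  non-overlapping size classes (one class per age, so size-dependent rates
  are not confounded by growth histories of different length), the
  first-year class being all newborns starting from the 5 mm hatch length;
* the heated-minus-reference difference series, split at the impact year.

Growth during an individual's survey (capture) year is never assessed --
it would depend on the within-year time of sampling -- but the partial
survey-year increment is carried in the increment table (flagged
``excluded``) so design summaries count the full coverage span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SizeClassSpec",
    "AnnualResponseSeries",
    "DifferenceSeries",
    "length_specific_growth",
    "increment_table",
    "select_size_class",
    "build_response_series",
    "difference_series",
]


def _default_classes() -> dict:
    # non-overlapping length windows, one per age; bounds chosen in the
    # field design so every (area, year) cell keeps N > 3
    return {1: (65.0, 75.0), 2: (110.0, 130.0), 3: (140.0, 160.0)}


@dataclass
class SizeClassSpec:
    """Size-class windows per age plus group-size rules.

    ``classes`` maps age -> closed interval [lower, upper] in mm; the age-0
    "class" is all newborns (hatch length).  Cells with fewer than
    ``n_min`` fish and cohorts with fewer than ``min_cohort_n`` aged
    individuals are dropped.
    """

    classes: dict = field(default_factory=_default_classes)
    hatch_mm: float = 5.0
    n_min: int = 4
    min_cohort_n: int = 3

    def validate(self) -> "SizeClassSpec":
        items = sorted(self.classes.items())
        for age, (lo, hi) in items:
            if not lo < hi:
                raise ValueError(f"size class for age {age}: lower must be < upper")
        for (_, (_, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
            if hi1 >= lo2:
                raise ValueError("size classes of successive ages must not overlap")
        return self


@dataclass
class AnnualResponseSeries:
    """Annual means of one response in one area: (year, mean, n)."""

    area: str
    name: str
    table: pd.DataFrame  # columns: year, mean, n


@dataclass
class DifferenceSeries:
    """Annual heated-minus-reference differences split at the impact year.

    ``onset_in_after`` controls whether the impact year itself is flagged
    as after (the default) or before (the inclusive accounting used for
    design-year counts).
    """

    name: str
    impact_year: int
    years: np.ndarray
    delta: np.ndarray
    onset_in_after: bool = True

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.delta = np.asarray(self.delta, dtype=float)
        order = np.argsort(self.years)
        self.years = self.years[order]
        self.delta = self.delta[order]

    @property
    def after(self) -> np.ndarray:
        if self.onset_in_after:
            return self.years >= self.impact_year
        return self.years > self.impact_year

    @property
    def n_before(self) -> int:
        return int((~self.after).sum())

    @property
    def n_after(self) -> int:
        return int(self.after.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "delta": self.delta, "after": self.after}
        )


def length_specific_growth(l_t, l_t_plus_1):
    """Length-specific annual growth G_L = (L_{t+1} - L_t) / L_t.

    Accepts scalars or arrays; raises for non-positive starting length and
    logs a warning if any growth value is negative (decreasing lengths).
    """
    l_t_arr = np.asarray(l_t, dtype=float)
    l_t1_arr = np.asarray(l_t_plus_1, dtype=float)
    if np.any(l_t_arr <= 0):
        raise ValueError("starting length must be positive")
    g = (l_t1_arr - l_t_arr) / l_t_arr
    if np.any(g < 0):
        logger.warning("negative length-specific growth encountered (decreasing lengths)")
    if np.ndim(l_t) == 0 and np.ndim(l_t_plus_1) == 0:
        return float(g)
    return g


def increment_table(
    lengths: pd.DataFrame, fish: pd.DataFrame, hatch_mm: float = 5.0
) -> pd.DataFrame:
    """Annual growth increments from a back-calculated length table.

    ``lengths`` is long format (fish_id, area, birth_year, age, year,
    length_mm) at ring ages 1..capture_age.  Produces one row per increment
    with the start-year convention (the increment from age a to a+1 is
    assigned to calendar year birth_year + a): the first-year increment
    from the hatch length, ring-to-ring increments, and the partial
    survey-year increment from the last ring to the capture length, which
    is flagged ``excluded=True`` and never used for growth analyses.
    """
    lengths = lengths[lengths["fish_id"].isin(fish["fish_id"])]
    lengths = lengths.sort_values(["fish_id", "age"])
    meta = fish.set_index("fish_id")

    grp = lengths.groupby("fish_id")
    l_start = grp["length_mm"].shift(1)
    first = grp.cumcount() == 0
    l_start = l_start.where(~first, hatch_mm)

    out = pd.DataFrame(
        {
            "fish_id": lengths["fish_id"].to_numpy(),
            "area": lengths["area"].to_numpy(),
            "birth_year": lengths["birth_year"].to_numpy(),
            "age": lengths["age"].to_numpy() - 1,  # start age of the increment
            "year": lengths["year"].to_numpy() - 1,
            "l_start_mm": l_start.to_numpy(),
            "l_end_mm": lengths["length_mm"].to_numpy(),
            "excluded": False,
        }
    )

    # partial survey-year increment: last ring -> measured capture length
    last = lengths.groupby("fish_id").tail(1)
    cap = meta.loc[last["fish_id"], ["capture_year", "capture_length_mm"]]
    partial = pd.DataFrame(
        {
            "fish_id": last["fish_id"].to_numpy(),
            "area": last["area"].to_numpy(),
            "birth_year": last["birth_year"].to_numpy(),
            "age": last["age"].to_numpy(),
            "year": cap["capture_year"].to_numpy(),
            "l_start_mm": last["length_mm"].to_numpy(),
            "l_end_mm": cap["capture_length_mm"].to_numpy(),
            "excluded": True,
        }
    )
    out = pd.concat([out, partial], ignore_index=True)
    out["g_l"] = (out["l_end_mm"] - out["l_start_mm"]) / out["l_start_mm"]
    return out.sort_values(["fish_id", "age"]).reset_index(drop=True)


def select_size_class(
    lengths: pd.DataFrame, age: int, spec: SizeClassSpec
) -> pd.DataFrame:
    """Fish whose back-calculated length at ``age`` falls in that age's class.

    Intervals are closed on both ends (boundary ties retained).  For age 0
    every fish qualifies (all newborns share the hatch length).  Cells
    (area, year at that age) with fewer than ``n_min`` fish are dropped and
    logged.
    """
    spec.validate()
    if age == 0:
        sel = lengths[lengths["age"] == 1][
            ["fish_id", "area", "birth_year"]
        ].drop_duplicates()
        sel = sel.assign(year=sel["birth_year"])
    else:
        if age not in spec.classes:
            raise KeyError(f"no size class defined for age {age}")
        lo, hi = spec.classes[age]
        at_age = lengths[lengths["age"] == age]
        sel = at_age[(at_age["length_mm"] >= lo) & (at_age["length_mm"] <= hi)][
            ["fish_id", "area", "birth_year", "year"]
        ]
    counts = sel.groupby(["area", "year"])["fish_id"].transform("size")
    dropped = sel[counts < spec.n_min]
    if len(dropped):
        cells = dropped[["area", "year"]].drop_duplicates()
        logger.info("dropping %d size-class cells with n < %d", len(cells), spec.n_min)
    return sel[counts >= spec.n_min].reset_index(drop=True)


def _drop_small_cohorts(fish: pd.DataFrame, min_cohort_n: int) -> pd.DataFrame:
    """Exclude birth years with too few aged individuals (per area)."""
    n = fish.groupby(["area", "birth_year"])["fish_id"].transform("size")
    return fish[n >= min_cohort_n]


def build_response_series(
    lengths: pd.DataFrame,
    increments: pd.DataFrame,
    fish: pd.DataFrame,
    response: str,
    spec: SizeClassSpec | None = None,
) -> dict[str, AnnualResponseSeries]:
    """Annual per-area means of one response.

    ``response`` is ``size_at_age_<k>`` (mean back-calculated length at age
    k, assigned to calendar year birth_year + k) or ``growth_ageclass_<k>``
    (mean G_L of the age-k increment among fish in the age-k size class,
    assigned to the increment's start year; age 0 means first-year growth
    of all newborns).  Survey-year increments are excluded, cohorts below
    the minimum size are dropped, and each reported cell carries its n
    (cells under n_min are dropped).
    """
    if spec is None:
        spec = SizeClassSpec()
    fish = _drop_small_cohorts(fish, spec.min_cohort_n)
    lengths = lengths[lengths["fish_id"].isin(fish["fish_id"])]
    increments = increments[increments["fish_id"].isin(fish["fish_id"])]

    if response.startswith("size_at_age_"):
        age = int(response.removesuffix("").rsplit("_", 1)[-1])
        data = lengths[lengths["age"] == age][["area", "year", "length_mm"]]
        value_col = "length_mm"
    elif response.startswith("growth_ageclass_"):
        age = int(response.rsplit("_", 1)[-1])
        members = select_size_class(lengths, age, spec)
        inc = increments[(increments["age"] == age) & (~increments["excluded"])]
        data = inc.merge(members[["fish_id"]], on="fish_id")[["area", "year", "g_l"]]
        value_col = "g_l"
    else:
        raise ValueError(f"unknown response {response!r}")

    agg = (
        data.groupby(["area", "year"])[value_col]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    agg = agg[agg["n"] >= spec.n_min]
    out = {}
    for area, sub in agg.groupby("area"):
        out[area] = AnnualResponseSeries(
            area=area,
            name=response,
            table=sub[["year", "mean", "n"]].reset_index(drop=True),
        )
    return out


def difference_series(
    heated: AnnualResponseSeries,
    reference: AnnualResponseSeries,
    impact_year: int,
    onset_in_after: bool = True,
) -> DifferenceSeries:
    """Heated-minus-reference differences on the years both areas report.

    Requires at least two before-years and two after-years in common;
    raises with the deficient period named otherwise.
    """
    merged = heated.table.merge(
        reference.table, on="year", suffixes=("_heated", "_reference")
    )
    years = merged["year"].to_numpy()
    after = years >= impact_year if onset_in_after else years > impact_year
    name = heated.name or reference.name
    for label, mask in (("before", ~after), ("after", after)):
        if mask.sum() < 2:
            raise ValueError(
                f"{name}: need >= 2 common {label}-impact years, found {int(mask.sum())}"
            )
    return DifferenceSeries(
        name=name,
        impact_year=impact_year,
        years=years,
        delta=(merged["mean_heated"] - merged["mean_reference"]).to_numpy(),
        onset_in_after=onset_in_after,
    )
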