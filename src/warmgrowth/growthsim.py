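"""Individual-based two-area growth and survey simulator.

Generates synthetic fish populations under a paired heated/reference design:
a shared reference temperature series (mean + trend + noise), a warming
offset added to the heated area from the impact year onward, annual growth
increments from a size-dependent thermal performance curve, a capture
schedule, gillnet size selectivity, the female-only ageing rule, and
length-stratified subsampling of aged fish in later survey years.  The two
areas share the reference noise stream by construction, so the paired
design's common-natural-variability assumption holds exactly.

Also generates survey catch records for the fish community (for the CPUE /
ordination branch of the analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from warmgrowth.config import AREAS, ConfigError, GrowthParams, SimulationConfig

__all__ = [
    "TemperatureSeries",
    "FishIndividual",
    "Population",
    "thermal_optimum",
    "growth_increment",
    "warming_offset",
    "generate_temperature_series",
    "simulate_population",
    "sample_catch",
    "simulate_catch_records",
]


@dataclass
class TemperatureSeries:
    """Annual mean growth-season temperature for one area."""

    area: str
    temps: pd.Series  # index: calendar year, values: degC

    def years(self) -> np.ndarray:
        return self.temps.index.to_numpy()

    def __getitem__(self, year: int) -> float:
        return float(self.temps.loc[year])


@dataclass
class FishIndividual:
    """One fish: provenance plus its true length-at-age trajectory."""

    fish_id: int
    area: str
    birth_year: int
    sex: str
    true_length_at_age: np.ndarray  # index = age, age 0 = hatch length
    capture_year: int
    capture_age: int
    capture_length: float


@dataclass
class Population:
    """Simulated fish of both areas.

    ``fish`` has one row per individual (fish_id, area, birth_year, sex,
    capture_year, capture_age, capture_length_mm); ``trajectories`` is long
    format (fish_id, area, birth_year, age, year, length_mm) with the true
    lengths at ages 0..capture_age.
    """

    fish: pd.DataFrame
    trajectories: pd.DataFrame
    temperature_heated: TemperatureSeries
    temperature_reference: TemperatureSeries
    config: SimulationConfig = field(repr=False)

    def individuals(self):
        """Yield FishIndividual objects (convenience view; tables are primary)."""
        traj = self.trajectories.sort_values(["fish_id", "age"])
        lengths = {
            fid: grp["length_mm"].to_numpy() for fid, grp in traj.groupby("fish_id")
        }
        for row in self.fish.itertuples():
            yield FishIndividual(
                fish_id=row.fish_id,
                area=row.area,
                birth_year=row.birth_year,
                sex=row.sex,
                true_length_at_age=lengths[row.fish_id],
                capture_year=row.capture_year,
                capture_age=row.capture_age,
                capture_length=row.capture_length_mm,
            )


# ---------------------------------------------------------------------------
# growth model
# ---------------------------------------------------------------------------


def thermal_optimum(length_mm, params: GrowthParams):
    """Size-dependent optimum temperature for growth (degC).

    Constant at theta0 for lengths at or below l_ref, declining
    logarithmically above it.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    rel = np.maximum(length_mm, params.l_ref_mm) / params.l_ref_mm
    return params.theta0_c - params.theta1_c * np.log(rel)


def growth_increment(length_mm, temperature_c, params: GrowthParams):
    """Annual length increment (mm) at the given length and temperature.

    increment = k * max(l_inf - L, 0) * exp(-((T - T_opt(L)) / w)**2);
    non-negative by construction, zero at the asymptotic length.
    """
    length_arr = np.asarray(length_mm, dtype=float)
    if np.any(length_arr <= 0):
        raise ValueError("length must be positive")
    g_max = params.k * np.maximum(params.l_inf_mm - length_arr, 0.0)
    z = (np.asarray(temperature_c, dtype=float) - thermal_optimum(length_arr, params)) / params.width_c
    out = g_max * np.exp(-(z**2))
    if np.ndim(length_mm) == 0 and np.ndim(temperature_c) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# temperature scenarios
# ---------------------------------------------------------------------------


def warming_offset(years, config: SimulationConfig) -> np.ndarray:
    """Heated-minus-reference temperature offset dT(year).

    Zero before the impact year; afterwards follows the configured warming
    form with s = year - impact_year:

    * step:        M
    * linear:      M * min(s / ramp_years, 1)
    * asymptotic:  M * s / (s + gamma)
    * sigmoid:     M / (1 + exp(-(s - tau) / gamma))
    * none:        0
    """
    years = np.asarray(years, dtype=float)
    s = years - config.impact_year
    after = s >= 0
    m = config.warming_magnitude
    p = config.warming_form_params
    form = config.warming_form
    if form == "none":
        dt = np.zeros_like(s)
    elif form == "step":
        dt = np.full_like(s, m)
    elif form == "linear":
        ramp = float(p.get("ramp_years", 24.0))
        dt = m * np.minimum(np.maximum(s, 0.0) / ramp, 1.0)
    elif form == "asymptotic":
        gamma = float(p.get("gamma", 3.0))
        dt = m * np.maximum(s, 0.0) / (np.maximum(s, 0.0) + gamma)
    elif form == "sigmoid":
        gamma = float(p.get("gamma", 3.0))
        tau = float(p.get("tau", 8.0))
        dt = m / (1.0 + np.exp(-(s - tau) / gamma))
    else:  # pragma: no cover - guarded by config.validate()
        raise ConfigError(f"unknown warming_form {form!r}")
    return np.where(after, dt, 0.0)


def _latent_temperatures(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True (latent) annual temperatures: shared stream + warming offset.

    Returns (years, heated, reference).  The latent series drive growth;
    both areas share one interannual noise stream and one trend
    coefficient by construction, so the paired design's common-variability
    assumption holds exactly.
    """
    years = np.arange(config.year_start, config.year_end + 1)
    noise = rng.normal(0.0, config.reference_temp_sd, size=years.size)
    ref = (
        config.reference_temp_mean
        + config.reference_temp_trend * (years - config.year_start)
        + noise
    )
    return years, ref + warming_offset(years, config), ref


def generate_temperature_series(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """Recorded reference and heated annual temperature series.

    The latent reference follows mean + trend*(year - year_start) + shared
    noise; the latent heated series is the same realization plus the
    warming offset.  The recorded series add independent measurement noise
    (``temp_obs_sd``) per area and year, as in any real monitoring record;
    with all noise terms zero, heated - reference equals the warming
    offset exactly.  Returns ``(heated, reference)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(4)[0])
    years, heat, ref = _latent_temperatures(config, rng)
    heat = heat + rng.normal(0.0, config.temp_obs_sd, size=years.size)
    ref = ref + rng.normal(0.0, config.temp_obs_sd, size=years.size)
    idx = pd.Index(years, name="year")
    return (
        TemperatureSeries("heated", pd.Series(heat, index=idx, name="temp_c")),
        TemperatureSeries("reference", pd.Series(ref, index=idx, name="temp_c")),
    )


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def _truncated_geometric_ages(
    n: int, survival: float, max_age: int, rng: np.random.Generator
) -> np.ndarray:
    """Capture ages 1..max_age with P(a) proportional to survival**(a-1)."""
    ages = np.arange(1, max_age + 1)
    w = survival ** (ages - 1)
    return rng.choice(ages, size=n, p=w / w.sum())


def _gradual_multiplier(
    area: str, year: np.ndarray, length: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Post-impact ramped multiplier on growth capacity for small heated fish."""
    if not config.gradual_effect_mode or area != "heated":
        return np.ones_like(length)
    frac = np.clip(
        (np.asarray(year, dtype=float) - config.impact_year)
        / config.gradual_effect_years,
        0.0,
        1.0,
    )
    small = length < config.gradual_effect_length_max_mm
    return np.where(small, 1.0 + config.gradual_effect_magnitude * frac, 1.0)


def simulate_population(config: SimulationConfig) -> Population:
    """Simulate both areas' populations over all cohorts.

    Each fish starts at the hatch length (5 mm), receives one growth
    increment per calendar year at its area's temperature (times its
    lifelong heterogeneity multiplier and a per-year lognormal shock), and
    is assigned a capture age from a truncated geometric schedule.  With all
    noise terms zero the simulation is deterministic.
    """
    config.validate()
    seqs = np.random.SeedSequence(config.rng_seed).spawn(4)
    rng_temp = np.random.default_rng(seqs[0])
    rng_pop = np.random.default_rng(seqs[1])

    # growth is driven by the latent temperatures; the recorded series
    # (returned on the Population) add independent measurement noise
    years_t, heat_lat, ref_lat = _latent_temperatures(config, rng_temp)
    idx = pd.Index(years_t, name="year")
    latent = {
        "heated": pd.Series(heat_lat, index=idx),
        "reference": pd.Series(ref_lat, index=idx),
    }
    heated = TemperatureSeries(
        "heated",
        pd.Series(
            heat_lat + rng_temp.normal(0.0, config.temp_obs_sd, size=years_t.size),
            index=idx,
            name="temp_c",
        ),
    )
    reference = TemperatureSeries(
        "reference",
        pd.Series(
            ref_lat + rng_temp.normal(0.0, config.temp_obs_sd, size=years_t.size),
            index=idx,
            name="temp_c",
        ),
    )
    gp = config.growth_params

    fish_rows = []
    traj_rows = []
    fish_id0 = 0
    birth_years = np.arange(config.year_start, config.year_end)  # last cohort year_end-1
    for area in AREAS:
        n = birth_years.size * config.recruits_per_year_per_area
        birth = np.repeat(birth_years, config.recruits_per_year_per_area)
        female = rng_pop.random(n) < config.female_fraction
        cap_age = _truncated_geometric_ages(
            n, config.annual_survival, config.max_age, rng_pop
        )
        cap_age = np.minimum(cap_age, config.year_end - birth)
        cap_age = np.maximum(cap_age, 1)

        if config.individual_growth_cv > 0:
            sd = np.sqrt(np.log1p(config.individual_growth_cv**2))
            het = rng_pop.lognormal(-0.5 * sd**2, sd, size=n)
        else:
            het = np.ones(n)

        temp_by_year = latent[area]
        lengths = np.full((n, config.max_age + 1), np.nan)
        lengths[:, 0] = gp.hatch_mm
        cur = lengths[:, 0].copy()
        for a in range(config.max_age):
            grow = a < cap_age
            year = birth + a
            t = temp_by_year.reindex(year).to_numpy()
            inc = growth_increment(cur, t, gp)
            inc *= het
            if config.annual_growth_cv > 0:
                sd_a = np.sqrt(np.log1p(config.annual_growth_cv**2))
                inc *= rng_pop.lognormal(-0.5 * sd_a**2, sd_a, size=n)
            inc *= _gradual_multiplier(area, year, cur, config)
            inc = np.maximum(inc, 1e-9)  # keep trajectories strictly increasing
            nxt = cur + inc
            lengths[grow, a + 1] = nxt[grow]
            cur = np.where(grow, nxt, cur)

        cap_true = lengths[np.arange(n), cap_age]
        cap_len = cap_true + rng_pop.normal(0.0, config.measurement_sd, size=n)
        cap_len = np.maximum(cap_len, 1.0)

        ids = fish_id0 + np.arange(n)
        fish_id0 += n
        fish_rows.append(
            pd.DataFrame(
                {
                    "fish_id": ids,
                    "area": area,
                    "birth_year": birth,
                    "sex": np.where(female, "F", "M"),
                    "capture_age": cap_age,
                    "capture_year": birth + cap_age,
                    "capture_length_mm": cap_len,
                }
            )
        )

        ages = np.arange(config.max_age + 1)
        keep = ages[None, :] <= cap_age[:, None]
        ii, aa = np.nonzero(keep)
        traj_rows.append(
            pd.DataFrame(
                {
                    "fish_id": ids[ii],
                    "area": area,
                    "birth_year": birth[ii],
                    "age": ages[aa],
                    "year": birth[ii] + ages[aa],
                    "length_mm": lengths[ii, aa],
                }
            )
        )

    return Population(
        fish=pd.concat(fish_rows, ignore_index=True),
        trajectories=pd.concat(traj_rows, ignore_index=True),
        temperature_heated=heated,
        temperature_reference=reference,
        config=config,
    )


# ---------------------------------------------------------------------------
# survey sampling of aged fish
# ---------------------------------------------------------------------------


def logistic_selectivity(length_mm, params) -> np.ndarray:
    """Retention probability of the survey gillnets at a given length."""
    length_mm = np.asarray(length_mm, dtype=float)
    return 1.0 / (1.0 + np.exp(-(length_mm - params.l50_mm) / params.slope_mm))


def sample_catch(
    population: Population,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    apply_selectivity: bool = True,
    stratify: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Select the aged/measured subsample of the simulated catch.

    Applies, in order: the female-only ageing rule, logistic gillnet size
    selectivity on capture length, and (for capture years from the
    stratification start year onward) a cap of ``stratified_subsample_n``
    fish per length bin per (area, year).  Returns the sampled fish table
    and a metadata dict of counts per stage.
    """
    if config is None:
        config = population.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(4)[2])
    fish = population.fish
    meta = {"n_total": len(fish)}

    fish = fish[fish["sex"] == "F"]
    meta["n_female"] = len(fish)

    if apply_selectivity:
        p = logistic_selectivity(
            fish["capture_length_mm"].to_numpy(), config.selectivity_params
        )
        fish = fish[rng.random(len(fish)) < p]
    meta["n_selected"] = len(fish)

    if stratify and len(fish):
        binned = fish.assign(
            _bin=np.floor(fish["capture_length_mm"] / config.length_bin_mm).astype(int)
        )
        late = binned["capture_year"] >= config.stratification_start_year
        keep_idx = list(binned.index[~late])
        cap = config.stratified_subsample_n
        for _, grp in binned[late].groupby(["area", "capture_year", "_bin"]):
            if len(grp) <= cap:
                keep_idx.extend(grp.index)
            else:
                keep_idx.extend(rng.choice(grp.index.to_numpy(), size=cap, replace=False))
        fish = fish.loc[sorted(keep_idx)]
    meta["n_sampled"] = len(fish)

    if len(fish) == 0:
        warnings.warn("sample_catch: no fish left after filters", stacklevel=2)
    return fish.reset_index(drop=True), meta


# ---------------------------------------------------------------------------
# community catch records
# ---------------------------------------------------------------------------


def _drift_factor(years: np.ndarray, shift: float, config: SimulationConfig) -> np.ndarray:
    """Per-species multiplicative abundance drift in the heated area."""
    cp = config.community
    s = np.asarray(years, dtype=float) - config.impact_year
    after = s >= 0
    if cp.drift_form == "none" or shift == 0.0:
        g = np.zeros_like(s)
    elif cp.drift_form == "step":
        g = np.ones_like(s)
    else:  # sigmoid
        g = 1.0 / (1.0 + np.exp(-(s - cp.drift_tau_years) / cp.drift_gamma_years))
    return np.exp(shift * np.where(after, g, 0.0))


def simulate_catch_records(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Survey catch records for both areas' community monitoring.

    One row per (area, year, station, night, species): Poisson counts
    around area-specific per-net-night rates, with optional post-impact
    compositional drift in the heated area.  Columns: area, year, month,
    station, night, species, count, nets.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(4)[3])
    cp = config.community
    years = np.arange(cp.year_start, config.year_end + 1)
    rows = []
    for area in AREAS:
        base = cp.baseline_heated if area == "heated" else cp.baseline_reference
        month = cp.month_heated if area == "heated" else cp.month_reference
        n_st = cp.n_stations_heated if area == "heated" else cp.n_stations_reference
        for species, lam in base.items():
            if area == "heated":
                drift = _drift_factor(years, cp.drift_shifts.get(species, 0.0), config)
            else:
                drift = np.ones_like(years, dtype=float)
            for st in range(1, n_st + 1):
                for night in range(1, cp.n_nights + 1):
                    counts = rng.poisson(lam * drift * cp.nets_per_station)
                    rows.append(
                        pd.DataFrame(
                            {
                                "area": area,
                                "year": years,
                                "month": month,
                                "station": st,
                                "night": night,
                                "species": species,
                                "count": counts,
                                "nets": cp.nets_per_station,
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)
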