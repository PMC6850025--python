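"""Validation experiments: model recovery, null calibration, round trips.

Seeded, scaled-down simulation experiments that characterize the
statistical machinery under the study design (12 before- and 24
after-impact years): how often each impact-response shape is recovered as
the Akaike-weight winner at a 3:1 effect:noise ratio, the type-I behavior
of the best-model p-value under no effect, the exactness of the
back-calculation round trip, and the no-warming calibration of the whole
pipeline.  Both the acceptance script and the test suite run these.
"""

from __future__ import annotations

import numpy as np

from warmgrowth import backcalc, growthsim
from warmgrowth.bacips import compare_models
from warmgrowth.config import SimulationConfig, null_scenario
from warmgrowth.growthstats import DifferenceSeries
from warmgrowth.pipeline import run_pipeline

__all__ = [
    "make_impact_series",
    "model_recovery",
    "null_selection_rejection",
    "backcalc_roundtrip_error",
    "pipeline_null_rejection",
]

# canonical generator shapes for the recovery experiment; chosen by a
# noiseless identifiability-margin analysis (each generator's AICc margin
# over every competitor positive at the design's n), see docs/methods.md
RECOVERY_SHAPES = {"asymptotic": {"gamma": 3.0}, "sigmoid": {"tau": 12.0, "gamma": 1.0}}


def make_impact_series(
    generator: str,
    rng: np.random.Generator,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    n_before: int = 12,
    n_after: int = 24,
    impact_year: int = 1980,
) -> DifferenceSeries:
    """One synthetic difference series under a known impact shape.

    ``generator`` is one of step/linear/asymptotic/sigmoid/none.  The
    effect is scaled so its maximum attained value equals ``amplitude``
    (the 3:1 amplitude:noise design at the defaults); the onset year
    counts as before, so after-years have s = 1..n_after.
    """
    years = np.arange(impact_year - n_before + 1, impact_year + n_after + 1)
    s = (years - impact_year).astype(float)
    after = years > impact_year
    f = np.zeros_like(s)
    sa = s[after]
    if generator == "step":
        f[after] = 1.0
    elif generator == "linear":
        f[after] = sa / n_after
    elif generator == "asymptotic":
        g = RECOVERY_SHAPES["asymptotic"]["gamma"]
        f[after] = (sa / (sa + g)) / (n_after / (n_after + g))
    elif generator == "sigmoid":
        tau = RECOVERY_SHAPES["sigmoid"]["tau"]
        g = RECOVERY_SHAPES["sigmoid"]["gamma"]
        f[after] = 1.0 / (1.0 + np.exp(-(sa - tau) / g))
    elif generator != "none":
        raise ValueError(f"unknown generator {generator!r}")
    delta = amplitude * f + rng.normal(0.0, noise_sd, size=years.size)
    return DifferenceSeries(
        name=generator,
        impact_year=impact_year,
        years=years,
        delta=delta,
        onset_in_after=False,
    )


def model_recovery(
    generator: str,
    n_replicates: int,
    rng: np.random.Generator,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
) -> float:
    """Fraction of replicates in which the generating model wins the weight."""
    wins = 0
    for _ in range(n_replicates):
        series = make_impact_series(generator, rng, amplitude, noise_sd)
        wins += compare_models(series).best.model == generator
    return wins / n_replicates


def null_selection_rejection(n_replicates: int, rng: np.random.Generator) -> float:
    """Fraction of no-effect replicates with best-model p below 0.05."""
    rejections = 0
    for _ in range(n_replicates):
        series = make_impact_series("none", rng, amplitude=0.0)
        rejections += compare_models(series).p_value < 0.05
    return rejections / n_replicates


def backcalc_roundtrip_error(n_fish: int = 1000, seed: int = 0) -> float:
    """Max |error| (mm) of the noise-free back-calculation round trip.

    Simulates trajectories, synthesizes annuli with zero radius noise and
    zero measurement noise, back-calculates with the true power relation,
    and returns the worst absolute deviation from the true lengths.
    """
    cfg = SimulationConfig(rng_seed=seed, measurement_sd=0.0, radius_noise_cv=0.0)
    cohorts = cfg.year_end - cfg.year_start
    cfg.recruits_per_year_per_area = max(1, int(np.ceil(n_fish / (2 * cohorts))))
    population = growthsim.simulate_population(cfg)
    fish = population.fish.head(n_fish)
    relation = backcalc.LengthRadiusRelation(cfg.relation_a, cfg.relation_b)
    annuli, fish = backcalc.synthesize_annuli_table(
        population.trajectories, fish, relation, radius_noise_cv=0.0
    )
    lengths = backcalc.backcalculate_table(annuli, fish, relation)
    truth = population.trajectories.merge(
        lengths, on=["fish_id", "age"], suffixes=("_true", "_bc")
    )
    return float(np.abs(truth["length_mm_true"] - truth["length_mm_bc"]).max())


def pipeline_null_rejection(
    n_runs: int, base_seed: int = 0, **config_overrides
) -> tuple[float, int]:
    """No-warming calibration of the whole pipeline.

    Runs the full chain under the null scenario for ``n_runs`` seeds and
    returns (fraction of analyzed responses with best-model p < 0.05,
    total number of response tests).  Under a well-calibrated analysis the
    fraction should sit near the nominal test level.
    """
    rejections = 0
    total = 0
    for i in range(n_runs):
        cfg = null_scenario(seed=(base_seed + i) % (2**31 - 1), **config_overrides)
        report = run_pipeline(cfg)
        for row in report.responses:
            total += 1
            rejections += row["p_value"] < 0.05
    return (rejections / total if total else float("nan")), total
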