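"""Operculum annuli and back-calculation of length-at-age.

The survey ages fish from winter year rings (annuli) in the operculum
bone.  Back-calculation follows the body proportional hypothesis (BPH) in
its power-function form: with the population relation L = a * R^b fitted by
log-log regression of capture length on capture radius, the BPH gives

    L_i = L_c * (R_i / R_c)**b

for the length at the i-th ring -- the coefficient a cancels, only the
exponent enters.  The inverse model (synthesize_annuli) generates radii
from true trajectories for the synthetic-data path, so the round trip
(zero noise, true relation) reproduces trajectories exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OperculumRecord",
    "LengthRadiusRelation",
    "SingularFitError",
    "synthesize_annuli",
    "synthesize_annuli_table",
    "fit_length_radius",
    "backcalculate_lengths",
    "backcalculate_table",
]


class SingularFitError(ValueError):
    """Raised when the length-radius regression is degenerate."""


@dataclass
class OperculumRecord:
    """Annuli radii and capture measurements for one fish.

    ``radii`` holds R_1..R_n (one per completed winter ring, strictly
    increasing); ``capture_radius`` is the operculum radius at capture and
    ``capture_length`` the measured body length (mm).
    """

    fish_id: int
    radii: np.ndarray
    capture_radius: float
    capture_length: float

    def validate(self) -> "OperculumRecord":
        r = np.asarray(self.radii, dtype=float)
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError(f"fish {self.fish_id}: radii must be positive and increasing")
        if r.size and r[-1] > self.capture_radius:
            raise ValueError(
                f"fish {self.fish_id}: last ring radius exceeds capture radius"
            )
        if self.capture_length <= 0:
            raise ValueError(f"fish {self.fish_id}: capture length must be positive")
        return self


@dataclass
class LengthRadiusRelation:
    """Power relation L = a * R^b with log-scale fit diagnostics."""

    a: float
    b: float
    n: int = 0
    log_resid_sd: float = 0.0

    def radius_for_length(self, length_mm):
        return (np.asarray(length_mm, dtype=float) / self.a) ** (1.0 / self.b)

    def length_for_radius(self, radius):
        return self.a * np.asarray(radius, dtype=float) ** self.b


def synthesize_annuli(
    individual,
    relation: LengthRadiusRelation,
    radius_noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> OperculumRecord:
    """Generate an operculum record from a true growth trajectory.

    Ring radii are the inverse of the power relation at the true lengths at
    ages 1..capture_age, perturbed by lognormal noise and re-sorted to keep
    them monotone; the capture radius derives from the capture length.
    """
    lengths = np.asarray(individual.true_length_at_age, dtype=float)
    if np.any(np.diff(lengths) <= 0):
        raise ValueError("trajectory must be strictly increasing")
    ring_lengths = lengths[1 : individual.capture_age + 1]
    radii = relation.radius_for_length(ring_lengths)
    r_c = float(relation.radius_for_length(individual.capture_length))
    if radius_noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng()
        sd = np.sqrt(np.log1p(radius_noise_cv**2))
        radii = radii * rng.lognormal(-0.5 * sd**2, sd, size=radii.size)
        r_c *= rng.lognormal(-0.5 * sd**2, sd)
        radii = np.sort(radii)
    r_c = max(r_c, radii[-1] if radii.size else r_c)
    return OperculumRecord(
        fish_id=individual.fish_id,
        radii=radii,
        capture_radius=r_c,
        capture_length=float(individual.capture_length),
    ).validate()


def synthesize_annuli_table(
    trajectories: pd.DataFrame,
    fish: pd.DataFrame,
    relation: LengthRadiusRelation,
    radius_noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized annuli synthesis for a sampled fish table.

    Returns ``(annuli, fish)`` where ``annuli`` has one row per
    (fish_id, age, radius) for ring ages 1..capture_age and ``fish`` gains a
    ``capture_radius`` column.  Radii are re-sorted per fish after noise.
    """
    if rng is None:
        rng = np.random.default_rng()
    traj = trajectories[trajectories["fish_id"].isin(fish["fish_id"])]
    rings = traj[traj["age"] >= 1].copy()
    radii = relation.radius_for_length(rings["length_mm"].to_numpy())
    if radius_noise_cv > 0:
        sd = np.sqrt(np.log1p(radius_noise_cv**2))
        radii = radii * rng.lognormal(-0.5 * sd**2, sd, size=radii.size)
    rings["radius"] = radii
    rings = rings.sort_values(["fish_id", "age"])
    # restore within-fish monotonicity disturbed by noise
    rings["radius"] = rings.groupby("fish_id")["radius"].transform(np.sort)

    fish = fish.copy()
    r_c = relation.radius_for_length(fish["capture_length_mm"].to_numpy())
    if radius_noise_cv > 0:
        sd = np.sqrt(np.log1p(radius_noise_cv**2))
        r_c = r_c * rng.lognormal(-0.5 * sd**2, sd, size=r_c.size)
    last_ring = rings.groupby("fish_id")["radius"].max()
    fish["capture_radius"] = np.maximum(
        r_c, last_ring.reindex(fish["fish_id"]).to_numpy()
    )
    annuli = rings[["fish_id", "area", "birth_year", "age", "year", "radius"]]
    return annuli.reset_index(drop=True), fish


def fit_length_radius(records) -> LengthRadiusRelation:
    """Fit L = a * R^b by OLS of ln(capture length) on ln(capture radius).

    ``records`` may be a sequence of OperculumRecord or a DataFrame with
    ``capture_radius`` and ``capture_length_mm`` (or ``capture_length``)
    columns.  Raises SingularFitError for degenerate inputs and warns when
    the estimated exponent is indistinguishable from zero.
    """
    if isinstance(records, pd.DataFrame):
        r = records["capture_radius"].to_numpy(dtype=float)
        col = "capture_length_mm" if "capture_length_mm" in records else "capture_length"
        length = records[col].to_numpy(dtype=float)
    else:
        records = list(records)
        r = np.array([rec.capture_radius for rec in records], dtype=float)
        length = np.array([rec.capture_length for rec in records], dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 records to fit the length-radius relation")
    if np.any(r <= 0) or np.any(length <= 0):
        raise ValueError("radii and lengths must be positive")
    if np.ptp(np.log(r)) < 1e-12:
        raise SingularFitError("all capture radii identical; relation not identifiable")
    fit = stats.linregress(np.log(r), np.log(length))
    resid = np.log(length) - (fit.intercept + fit.slope * np.log(r))
    rel = LengthRadiusRelation(
        a=float(np.exp(fit.intercept)),
        b=float(fit.slope),
        n=int(r.size),
        log_resid_sd=float(np.std(resid, ddof=2)) if r.size > 2 else 0.0,
    )
    if abs(rel.b) <= 2.0 * (fit.stderr or 0.0) or rel.b <= 0:
        warnings.warn(
            f"length-radius exponent b={rel.b:.3g} not distinguishable from zero",
            stacklevel=2,
        )
    return rel


def backcalculate_lengths(
    record: OperculumRecord,
    relation: LengthRadiusRelation,
    hatch_floor: float | None = None,
) -> np.ndarray:
    """Back-calculate length at each ring age under the BPH power form.

    L_i = L_c * (R_i / R_c)**b.  With ``hatch_floor`` set, lengths are
    floored at that value (off by default so exact round trips stay exact).
    """
    record.validate()
    radii = np.asarray(record.radii, dtype=float)
    if np.any(radii > record.capture_radius):
        raise ValueError("ring radius exceeds capture radius")
    lengths = record.capture_length * (radii / record.capture_radius) ** relation.b
    if hatch_floor is not None:
        lengths = np.maximum(lengths, hatch_floor)
    return lengths


def backcalculate_table(
    annuli: pd.DataFrame,
    fish: pd.DataFrame,
    relations: dict[str, LengthRadiusRelation] | LengthRadiusRelation,
) -> pd.DataFrame:
    """Back-calculate lengths for a whole annuli table.

    ``relations`` is either one pooled relation or a per-area dict (the
    default in the pipeline: opercula may scale differently across thermal
    regimes).  Returns long format (fish_id, area, birth_year, age, year,
    length_mm) with back-calculated lengths at ring ages.
    """
    merged = annuli.merge(
        fish[["fish_id", "capture_radius", "capture_length_mm"]], on="fish_id"
    )
    if isinstance(relations, LengthRadiusRelation):
        b = np.full(len(merged), relations.b)
    else:
        b = merged["area"].map({a: rel.b for a, rel in relations.items()}).to_numpy()
    ratio = merged["radius"].to_numpy() / merged["capture_radius"].to_numpy()
    if np.any(ratio > 1.0 + 1e-9):
        raise ValueError("ring radius exceeds capture radius")
    merged["length_mm"] = merged["capture_length_mm"].to_numpy() * np.minimum(ratio, 1.0) ** b
    return merged[["fish_id", "area", "birth_year", "age", "year", "length_mm"]]
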