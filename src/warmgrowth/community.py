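"""CPUE matrices, Chord distance and principal coordinates analysis.

The fish community branch of the analysis: catch per unit effort per
species (fish per net per night, first fishing night only, area-specific
survey month), a single ordination of both areas' species-by-year CPUE
using Chord distance (the Euclidean distance between unit-normalized year
vectors, a metric index insensitive to varying total abundance), and
per-axis heated-minus-reference difference series for BACIPS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from warmgrowth.growthstats import DifferenceSeries

__all__ = [
    "CpueFilters",
    "CommunityMatrix",
    "PCoAResult",
    "EffortError",
    "compute_cpue",
    "chord_distance_matrix",
    "pcoa",
    "orient_axes",
    "ordinate_community",
    "axis_difference_series",
]


class EffortError(ValueError):
    """Raised when filters leave zero fishing effort for some (area, year)."""


@dataclass
class CpueFilters:
    """Record filters applied before CPUE computation.

    ``months`` maps area -> survey month used for that area;
    ``stations`` maps area -> list of stations retained (None = all);
    ``exclude_species`` removes species not representatively sampled by
    the gear; ``exclude_samples`` drops disturbed (area, year) samples.
    """

    first_night_only: bool = True
    months: dict | None = None
    stations: dict | None = None
    exclude_species: tuple = ()
    exclude_samples: tuple = ()  # iterable of (area, year)


@dataclass
class CommunityMatrix:
    """Species-by-(area, year) CPUE with the filters that produced it."""

    cpue: pd.DataFrame  # index: (area, year) MultiIndex, columns: species
    filters: CpueFilters = field(default_factory=CpueFilters)

    @property
    def areas(self):
        return sorted(self.cpue.index.get_level_values("area").unique())


@dataclass
class PCoAResult:
    """Principal coordinates of the community distance matrix.

    ``scores`` holds sample coordinates on the retained (positive
    eigenvalue) axes PCO1, PCO2, ...; ``eigenvalues`` includes negative
    ones (reported, not dropped); ``proportions`` are eigenvalue shares of
    the positive total.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportions: np.ndarray


def compute_cpue(
    catch_records: pd.DataFrame, filters: CpueFilters | None = None
) -> CommunityMatrix:
    """Species-specific CPUE per (area, year): total count / net-nights.

    Applies the first-night rule, the area-specific survey month, station
    inclusion lists, species exclusions and disturbed-sample exclusions.
    Only species occurring in both areas' filtered records are retained.
    Raises EffortError naming the (area, year) if filters leave no effort.
    """
    if filters is None:
        filters = CpueFilters()
    rec = catch_records.copy()
    years_expected = rec.groupby("area")["year"].unique().to_dict()

    if filters.first_night_only and "night" in rec:
        rec = rec[rec["night"] == 1]
    if filters.months and "month" in rec:
        keep = pd.Series(False, index=rec.index)
        for area, month in filters.months.items():
            keep |= (rec["area"] == area) & (rec["month"] == month)
        keep |= ~rec["area"].isin(list(filters.months))
        rec = rec[keep]
    if filters.stations:
        keep = pd.Series(True, index=rec.index)
        for area, stations in filters.stations.items():
            keep &= (rec["area"] != area) | rec["station"].isin(list(stations))
        rec = rec[keep]
    if filters.exclude_species:
        rec = rec[~rec["species"].isin(list(filters.exclude_species))]
    for area, year in filters.exclude_samples:
        rec = rec[~((rec["area"] == area) & (rec["year"] == year))]

    for area, years in years_expected.items():
        still = set(rec.loc[rec["area"] == area, "year"])
        missing = sorted(
            set(int(y) for y in years) - still - {int(y) for _, y in filters.exclude_samples}
        )
        if missing:
            raise EffortError(
                f"zero effort after filters for area={area!r}, years {missing}"
            )

    # effort: net-nights per (area, year) = nets summed over distinct
    # (station, night) sampling events
    events = rec.drop_duplicates(["area", "year", "station", "night"])
    effort = events.groupby(["area", "year"])["nets"].sum()
    counts = rec.groupby(["area", "year", "species"])["count"].sum()
    cpue = (counts / effort).unstack("species", fill_value=0.0)

    # retain species present in both areas' programs
    present = (cpue.groupby(level="area").sum() > 0).all(axis=0)
    cpue = cpue.loc[:, present[present].index]
    return CommunityMatrix(cpue=cpue.sort_index(), filters=filters)


def chord_distance_matrix(matrix) -> pd.DataFrame:
    """Pairwise Chord distances between (area, year) CPUE rows.

    d(x, y) = || x/||x|| - y/||y|| ||_2, bounded by sqrt(2); invariant to
    row scaling.  Raises for all-zero rows (normalization undefined).
    """
    x = matrix.cpue if isinstance(matrix, CommunityMatrix) else matrix
    values = np.asarray(x, dtype=float)
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0):
        bad = np.nonzero(norms == 0)[0]
        idx = x.index[bad].tolist() if hasattr(x, "index") else bad.tolist()
        raise ValueError(f"all-zero community rows (undefined Chord distance): {idx}")
    normalized = values / norms[:, None]
    d = squareform(pdist(normalized, metric="euclidean"))
    index = x.index if hasattr(x, "index") else pd.RangeIndex(len(values))
    return pd.DataFrame(d, index=index, columns=index)


def pcoa(distance_matrix, eig_tol: float = 1e-12) -> PCoAResult:
    """Metric multidimensional scaling of a distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues, proportions of variation are shares of the
    positive-eigenvalue total, and negative eigenvalues are reported.
    """
    d = (
        distance_matrix.to_numpy()
        if isinstance(distance_matrix, pd.DataFrame)
        else np.asarray(distance_matrix, dtype=float)
    )
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    scale = max(abs(evals[0]), 1.0)
    pos = evals > eig_tol * scale
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    proportions = evals[pos] / evals[pos].sum()

    index = (
        distance_matrix.index
        if isinstance(distance_matrix, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    scores = pd.DataFrame(
        coords, index=index, columns=[f"PCO{i + 1}" for i in range(coords.shape[1])]
    )
    return PCoAResult(scores=scores, eigenvalues=evals, proportions=proportions)


def orient_axes(result: PCoAResult, matrix: CommunityMatrix) -> PCoAResult:
    """Fix eigenvector sign arbitrariness.

    Each axis is flipped, if needed, so the loading (covariance between the
    row-normalized abundance of the most abundant species and the axis
    scores) is non-negative; this makes axis difference series
    reproducible across runs and library versions.
    """
    cpue = matrix.cpue.loc[result.scores.index]
    dominant = cpue.sum(axis=0).idxmax()
    normalized = cpue.div(np.linalg.norm(cpue.to_numpy(), axis=1), axis=0)
    col = normalized[dominant] - normalized[dominant].mean()
    scores = result.scores.copy()
    for axis in scores.columns:
        loading = float(col @ (scores[axis] - scores[axis].mean()))
        if loading < 0:
            scores[axis] = -scores[axis]
    return PCoAResult(
        scores=scores, eigenvalues=result.eigenvalues, proportions=result.proportions
    )


def ordinate_community(matrix: CommunityMatrix) -> PCoAResult:
    """Chord-distance PCoA of a CPUE matrix with fixed axis orientation."""
    return orient_axes(pcoa(chord_distance_matrix(matrix)), matrix)


def axis_difference_series(
    result: PCoAResult,
    axis: int,
    impact_year: int,
    areas: tuple = ("heated", "reference"),
    onset_in_after: bool = True,
) -> DifferenceSeries:
    """Heated-minus-reference score differences on one ordination axis.

    Requires scores for at least two before- and two after-impact years in
    both areas.  Axis sign indeterminacy is handled upstream by the fixed
    orientation rule; flipping an axis negates the series but leaves its
    magnitude and BACIPS model choice unchanged.
    """
    col = f"PCO{axis}"
    if col not in result.scores.columns:
        raise KeyError(f"axis {col} not present ({list(result.scores.columns)})")
    wide = result.scores[col].unstack(level="area" if "area" in result.scores.index.names else 0)
    sub = wide[list(areas)].dropna()
    years = sub.index.to_numpy(dtype=int)
    after = years >= impact_year if onset_in_after else years > impact_year
    for label, mask in (("before", ~after), ("after", after)):
        if mask.sum() < 2:
            raise ValueError(
                f"PCO{axis}: need >= 2 {label}-impact years with scores in both areas"
            )
    return DifferenceSeries(
        name=f"pco{axis}",
        impact_year=impact_year,
        years=years,
        delta=(sub[areas[0]] - sub[areas[1]]).to_numpy(),
        onset_in_after=onset_in_after,
    )
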