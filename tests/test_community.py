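"""Community branch: CPUE, Chord distance, PCoA, axis differences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from warmgrowth import community
from warmgrowth.community import CommunityMatrix, CpueFilters, EffortError


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["area", "year", "month", "station", "night", "species", "count", "nets"],
    )


class TestComputeCpue:
    def test_count_over_net_nights(self):
        rec = _records(
            [
                ("heated", 2000, 10, 1, 1, "perch", 30, 2),
                ("reference", 2000, 8, 1, 1, "perch", 10, 2),
            ]
        )
        out = community.compute_cpue(rec)
        assert out.cpue.loc[("heated", 2000), "perch"] == pytest.approx(15.0)

    def test_second_night_excluded(self):
        rec = _records(
            [
                ("heated", 2000, 10, 1, 1, "perch", 30, 2),
                ("heated", 2000, 10, 1, 2, "perch", 500, 2),
                ("reference", 2000, 8, 1, 1, "perch", 10, 2),
            ]
        )
        out = community.compute_cpue(rec)
        assert out.cpue.loc[("heated", 2000), "perch"] == pytest.approx(15.0)

    def test_mixed_table_matches_hand_computation(self):
        rec = _records(
            [
                ("heated", 2000, 10, 1, 1, "perch", 12, 2),
                ("heated", 2000, 10, 2, 1, "perch", 6, 2),
                ("heated", 2000, 10, 1, 1, "roach", 8, 2),
                ("reference", 2000, 8, 1, 1, "perch", 9, 3),
                ("reference", 2000, 8, 1, 1, "roach", 3, 3),
            ]
        )
        out = community.compute_cpue(rec)
        # heated effort: stations 1 and 2, 2 nets each = 4 net-nights
        assert out.cpue.loc[("heated", 2000), "perch"] == pytest.approx(18 / 4)
        assert out.cpue.loc[("heated", 2000), "roach"] == pytest.approx(8 / 4)
        assert out.cpue.loc[("reference", 2000), "perch"] == pytest.approx(9 / 3)

    def test_month_and_station_filters(self):
        rec = _records(
            [
                ("heated", 2000, 10, 1, 1, "perch", 10, 2),
                ("heated", 2000, 8, 1, 1, "perch", 99, 2),  # wrong month
                ("heated", 2000, 10, 4, 1, "perch", 99, 2),  # excluded station
                ("reference", 2000, 8, 1, 1, "perch", 4, 2),
            ]
        )
        filters = CpueFilters(
            months={"heated": 10, "reference": 8}, stations={"heated": [1, 2, 3]}
        )
        out = community.compute_cpue(rec, filters)
        assert out.cpue.loc[("heated", 2000), "perch"] == pytest.approx(5.0)

    def test_species_must_occur_in_both_areas(self):
        rec = _records(
            [
                ("heated", 2000, 10, 1, 1, "perch", 10, 2),
                ("heated", 2000, 10, 1, 1, "carp", 5, 2),
                ("reference", 2000, 8, 1, 1, "perch", 4, 2),
                ("reference", 2000, 8, 1, 1, "carp", 0, 2),
            ]
        )
        out = community.compute_cpue(rec)
        assert list(out.cpue.columns) == ["perch"]

    def test_zero_effort_raises_with_location(self):
        rec = _records(
            [
                ("heated", 2000, 10, 1, 2, "perch", 10, 2),  # only night 2
                ("reference", 2000, 8, 1, 1, "perch", 4, 2),
            ]
        )
        with pytest.raises(EffortError, match="heated"):
            community.compute_cpue(rec)


class TestChordDistance:
    def test_proportional_rows_distance_zero(self):
        m = pd.DataFrame([[2.0, 2.0], [5.0, 5.0]])
        d = community.chord_distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_maximum(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        d = community.chord_distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_worked_value(self):
        m = pd.DataFrame([[1.0, 0.0], [1.0, 1.0]])
        d = community.chord_distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(2.0 - np.sqrt(2.0)), rel=1e-9)
        assert d.iloc[0, 1] == pytest.approx(0.76537, abs=1e-5)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            community.chord_distance_matrix(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.floats(0.0, 100.0), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        ),
        scales=st.lists(st.floats(0.1, 50.0), min_size=6, max_size=6),
    )
    def test_range_and_scale_invariance(self, data, scales):
        m = np.asarray(data) + 1e-3  # keep rows nonzero
        d = community.chord_distance_matrix(pd.DataFrame(m)).to_numpy()
        assert (d >= -1e-12).all() and (d <= np.sqrt(2) + 1e-9).all()
        scaled = m * np.asarray(scales[: m.shape[0]])[:, None]
        d2 = community.chord_distance_matrix(pd.DataFrame(scaled)).to_numpy()
        np.testing.assert_allclose(d2, d, atol=1e-9)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(pts))
        res = community.pcoa(d)
        assert res.proportions[0] == pytest.approx(1.0, abs=1e-9)

    def test_embedding_roundtrip(self, rng):
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        res = community.pcoa(d)
        d2 = squareform(pdist(res.scores.to_numpy()))
        np.testing.assert_allclose(d2, d, atol=1e-9)

    def test_chord_distances_euclidean_embeddable(self, rng):
        # chord distance is Euclidean between normalized rows, so the
        # Gower matrix must be PSD up to round-off
        for _ in range(20):
            m = rng.uniform(0.01, 10.0, size=(8, 5))
            d = community.chord_distance_matrix(pd.DataFrame(m))
            res = community.pcoa(d)
            assert res.eigenvalues.min() > -1e-9 * max(res.eigenvalues.max(), 1.0)

    def test_proportions_ordered_and_bounded(self, rng):
        m = rng.uniform(0.1, 5.0, size=(9, 4))
        res = community.pcoa(community.chord_distance_matrix(pd.DataFrame(m)))
        p = res.proportions
        assert (np.diff(p) <= 1e-12).all()
        assert (p >= 0).all()
        assert p.sum() <= 1.0 + 1e-9

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        ours = community.pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d), method="eigh")
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1][:3],
            np.sort(theirs.eigvals.to_numpy())[::-1][:3],
            atol=1e-8,
        )
        for axis in range(3):
            a = ours.scores.to_numpy()[:, axis]
            b = theirs.samples.to_numpy()[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_equals_pca_on_euclidean_distances(self, rng):
        # PCoA of Euclidean distances of row-normalized data = PCA scores
        m = rng.uniform(0.1, 5.0, size=(6, 4))
        norm = m / np.linalg.norm(m, axis=1, keepdims=True)
        res = community.pcoa(squareform(pdist(norm)))
        centered = norm - norm.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        pca_scores = u * s
        for axis in range(min(3, res.scores.shape[1])):
            a = res.scores.to_numpy()[:, axis]
            b = pca_scores[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            community.pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


def _two_area_matrix(heated, reference, years, species=("perch", "roach", "smelt")):
    idx = pd.MultiIndex.from_product(
        [["heated", "reference"], years], names=["area", "year"]
    )
    data = np.vstack([heated, reference])
    return CommunityMatrix(cpue=pd.DataFrame(data, index=idx, columns=species))


class TestAxisDifferences:
    def test_identical_trajectories_zero_difference(self, rng):
        years = range(1976, 1986)
        block = rng.uniform(1, 10, size=(10, 3))
        matrix = _two_area_matrix(block, block, years)
        res = community.ordinate_community(matrix)
        d = community.axis_difference_series(res, 1, 1980)
        np.testing.assert_allclose(d.delta, 0.0, atol=1e-9)

    def test_post_impact_shift_detected(self, rng):
        years = list(range(1974, 1990))
        heated = rng.uniform(4, 6, size=(16, 3))
        heated[6:, 2] *= 8.0  # composition shifts from 1980 onward
        reference = rng.uniform(4, 6, size=(16, 3))
        matrix = _two_area_matrix(heated, reference, years)
        res = community.ordinate_community(matrix)
        d = community.axis_difference_series(res, 1, 1980)
        assert np.abs(d.delta[d.after]).mean() > 3 * np.abs(d.delta[~d.after]).mean()

    def test_sign_flip_symmetry(self, rng):
        years = range(1976, 1986)
        matrix = _two_area_matrix(
            rng.uniform(1, 10, size=(10, 3)), rng.uniform(1, 10, size=(10, 3)), years
        )
        res = community.pcoa(community.chord_distance_matrix(matrix))
        flipped = community.PCoAResult(
            scores=-res.scores, eigenvalues=res.eigenvalues, proportions=res.proportions
        )
        d1 = community.axis_difference_series(res, 1, 1980)
        d2 = community.axis_difference_series(flipped, 1, 1980)
        np.testing.assert_allclose(d2.delta, -d1.delta, atol=1e-12)

    def test_orientation_rule_fixes_sign(self, rng):
        years = range(1976, 1986)
        matrix = _two_area_matrix(
            rng.uniform(1, 10, size=(10, 3)), rng.uniform(1, 10, size=(10, 3)), years
        )
        res = community.pcoa(community.chord_distance_matrix(matrix))
        flipped = community.PCoAResult(-res.scores, res.eigenvalues, res.proportions)
        o1 = community.orient_axes(res, matrix)
        o2 = community.orient_axes(flipped, matrix)
        pd.testing.assert_frame_equal(o1.scores, o2.scores)

    def test_missing_axis_rejected(self, rng):
        years = range(1976, 1986)
        matrix = _two_area_matrix(
            rng.uniform(1, 10, size=(10, 3)), rng.uniform(1, 10, size=(10, 3)), years
        )
        res = community.ordinate_community(matrix)
        with pytest.raises(KeyError):
            community.axis_difference_series(res, 99, 1980)
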