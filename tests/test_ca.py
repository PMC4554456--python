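"""Correspondence analysis against an independent chi-square oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colitype import (
    NoiseModel,
    default_templates,
    fit_ca,
    plane_summary,
    project_supplementary,
    simulate_cohort,
)
from colitype.pipeline import classify_samples, quantify_counts
from colitype.classify import drop_empty_columns


def pearson_chi_square(table: np.ndarray) -> float:
    """Independent oracle: sum over cells of (observed-expected)^2/expected."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    return float(((table - expected) ** 2 / expected).sum())


def random_table(rng, max_dim=8):
    """Random small non-negative integer table without zero rows/columns."""
    while True:
        shape = (rng.integers(2, max_dim + 1), rng.integers(2, max_dim + 1))
        table = rng.integers(0, 11, size=shape)
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            return table


class TestFitCA:
    def test_perfect_independence_has_zero_inertia(self):
        result = fit_ca(np.array([[10, 10], [10, 10]]))
        assert result.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert result.n_axes == 0

    def test_diagonal_table_has_unit_inertia_on_one_axis(self):
        result = fit_ca(np.array([[10, 0], [0, 10]]))
        assert result.total_inertia == 1.0
        assert result.n_axes == 1
        assert result.inertia_fractions[0] == pytest.approx(1.0)

    def test_total_inertia_matches_chi_square_oracle(self, rng):
        for _ in range(50):
            table = random_table(rng)
            result = fit_ca(table)
            assert result.total_inertia * table.sum() == pytest.approx(
                pearson_chi_square(table), abs=1e-10
            )

    def test_matches_scipy_chi2_statistic(self, rng):
        # cross-check against an independently implemented chi-square
        table = random_table(rng) + 1
        result = fit_ca(table)
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert result.total_inertia * table.sum() == pytest.approx(chi2, rel=1e-10)

    def test_inertia_equals_sum_of_principal_inertias(self, rng):
        table = random_table(rng)
        result = fit_ca(table)
        assert result.total_inertia == pytest.approx(
            result.principal_inertias.sum(), abs=1e-9
        )
        assert np.all(np.diff(result.singular_values) <= 1e-12)

    def test_row_coordinates_centered_and_orthogonal(self, rng):
        for _ in range(10):
            table = random_table(rng)
            result = fit_ca(table)
            coords, masses = result.row_coordinates, result.row_masses
            # mass-weighted centroid at the origin
            assert np.allclose(masses @ coords, 0.0, atol=1e-9)
            # axes uncorrelated under row masses, variance = inertia
            gram = (coords * masses[:, None]).T @ coords
            assert np.allclose(
                gram, np.diag(result.principal_inertias), atol=1e-8
            )

    def test_all_zero_row_and_column_named(self):
        frame = pd.DataFrame(
            [[1, 2], [0, 0], [3, 1]], index=["a", "bad", "c"], columns=["x", "y"]
        )
        with pytest.raises(ValueError, match="bad"):
            fit_ca(frame)
        frame = pd.DataFrame(
            [[1, 0, 2], [3, 0, 1]], index=["a", "b"], columns=["x", "empty", "y"]
        )
        with pytest.raises(ValueError, match="empty"):
            fit_ca(frame)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_ca(np.array([[1, -1], [2, 3]]))

    def test_sign_convention_is_reproducible(self, rng):
        table = random_table(rng)
        a, b = fit_ca(table), fit_ca(table)
        assert np.array_equal(a.row_coordinates, b.row_coordinates)
        for k in range(a.n_axes):
            i = np.argmax(np.abs(a.row_standard_coordinates[:, k]))
            assert a.row_standard_coordinates[i, k] > 0


class TestSupplementaryProjection:
    def test_refitting_training_rows_reproduces_coordinates(self, rng):
        table = random_table(rng) + 1
        result = fit_ca(table)
        projected = project_supplementary(result, table)
        assert np.allclose(projected, result.row_coordinates, atol=1e-9)

    def test_duplicate_row_projects_identically(self, rng):
        table = random_table(rng) + 1
        result = fit_ca(table)
        projected = project_supplementary(result, table[0:1])
        assert np.allclose(projected[0], result.row_coordinates[0], atol=1e-9)

    def test_column_mass_profile_projects_to_origin(self):
        table = np.array([[8, 2, 3], [1, 7, 2], [2, 2, 9]])
        result = fit_ca(table)
        projected = project_supplementary(result, result.column_masses[None, :])
        assert np.allclose(projected, 0.0, atol=1e-9)

    def test_column_mismatch_rejected(self, rng):
        table = random_table(rng) + 1
        result = fit_ca(table)
        with pytest.raises(ValueError, match="columns"):
            project_supplementary(result, np.ones((1, table.shape[1] + 1)))

    def test_zero_sum_row_rejected(self, rng):
        table = random_table(rng) + 1
        result = fit_ca(table)
        with pytest.raises(ValueError, match="positive sum"):
            project_supplementary(result, np.zeros((1, table.shape[1])))


class TestPlaneSummary:
    def test_sums_requested_axes(self):
        table = np.array([[10, 1, 1, 2], [1, 12, 2, 1], [2, 1, 9, 1], [1, 2, 1, 8]])
        result = fit_ca(table)
        f12 = plane_summary(result, (1, 2))
        assert f12 == pytest.approx(
            result.inertia_fractions[0] + result.inertia_fractions[1]
        )
        assert plane_summary(result, tuple(range(1, result.n_axes + 1))) == \
            pytest.approx(1.0)

    def test_single_axis_result(self):
        result = fit_ca(np.array([[10, 0], [0, 10]]))
        assert plane_summary(result, (1,)) == pytest.approx(1.0)

    def test_out_of_range_axis_rejected(self):
        result = fit_ca(np.array([[10, 0], [0, 10]]))
        with pytest.raises(IndexError):
            plane_summary(result, (1, 2))

    def test_f1_f2_fraction_stable_across_reruns(self):
        """Synthetic E1/E2/E3 cohort: the F1-F2 inertia fraction is
        deterministic given the seed."""
        noise = NoiseModel()
        templates = default_templates()[:3]

        def run():
            cohort = simulate_cohort(templates, 50, noise, seed=42)
            profiles = quantify_counts([q for _, _, q in cohort], noise)
            _, _, table = classify_samples(profiles, [h for h, _, _ in cohort])
            pruned, _ = drop_empty_columns(table)
            return plane_summary(fit_ca(pruned), (1, 2))

        first, second = run(), run()
        assert first == second
        assert 0.0 < first <= 1.0


class TestGroupSeparation:
    def test_enterocolitype_centroids_separate_on_f1_f2(self):
        """Zero-noise three-template animal cohort: within-group spread on
        the F1-F2 plane is smaller than between-centroid distances."""
        noise = NoiseModel(log10_measurement_sd=0.0)
        cohort = simulate_cohort(default_templates()[:3], 40, noise, seed=13)
        profiles = quantify_counts([q for _, _, q in cohort], noise)
        _, _, table = classify_samples(profiles, [h for h, _, _ in cohort])
        pruned, _ = drop_empty_columns(table)
        result = fit_ca(pruned)
        coords = result.row_coordinates[:, :2]
        labels = np.array([lab.split("_")[0] for lab in result.row_labels])
        centroids = {g: coords[labels == g].mean(axis=0) for g in ("E1", "E2", "E3")}
        spreads = {
            g: np.linalg.norm(coords[labels == g] - centroids[g], axis=1).mean()
            for g in centroids
        }
        pairs = [("E1", "E2"), ("E1", "E3"), ("E2", "E3")]
        for a, b in pairs:
            dist = np.linalg.norm(centroids[a] - centroids[b])
            assert dist > 1e-6  # pairwise distinct
            assert dist > max(spreads[a], spreads[b])
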