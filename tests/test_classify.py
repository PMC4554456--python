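"""Abundance categories, CFU classes, enterocolitypes, indicator tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colitype import (
    ANIMAL32_COLUMNS,
    STRAIN33_COLUMNS,
    NoiseModel,
    PhylogroupProfile,
    apply_detection_thresholds,
    build_indicator_table,
    build_phenotype,
    categorize_phylogroup,
    classify_cfu,
    compute_proportions,
    default_templates,
    host_for_species,
    reconstruct_panel,
    simulate_cohort,
)
from colitype.classify import drop_empty_columns
from colitype.datasets import load_b2_panel


def _profile(sample_id="s", p_a=0.0, p_a1=0.0, p_b1=0.0, p_b2=0.0, p_d=0.0,
             detected=None):
    if detected is None:
        detected = {
            "A": p_a >= 0.15,
            "B1": p_b1 >= 0.001,
            "B2": p_b2 >= 0.001,
            "D": p_d >= 0.001,
        }
    return PhylogroupProfile(
        sample_id=sample_id, p_a=p_a, p_a1=p_a1, p_a0=p_a - p_a1,
        p_b1=p_b1, p_b2=p_b2, p_d=p_d, detected=detected,
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "proportion,detected,expected",
        [
            (0.60, True, "dominant"),
            (0.51, True, "dominant"),
            (0.50, True, "intermediate"),  # dominant is strictly >50%
            (0.10, True, "intermediate"),  # intermediate is closed [10%, 50%]
            (0.099, True, "minor"),
            (0.05, True, "minor"),
            (0.30, False, "absent"),  # undetected wins over the number
            (0.0, True, "minor"),
        ],
    )
    def test_category_rules(self, proportion, detected, expected):
        assert categorize_phylogroup(proportion, detected) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_phylogroup(1.2, True)
        with pytest.raises(ValueError):
            categorize_phylogroup(-0.1, True)

    @given(
        p=st.floats(0, 1, allow_nan=False),
        detected=st.booleans(),
    )
    @settings(deadline=None, max_examples=200)
    def test_total_and_single_valued(self, p, detected):
        assert categorize_phylogroup(p, detected) in (
            "dominant", "intermediate", "minor", "absent"
        )


class TestCfuClass:
    @pytest.mark.parametrize(
        "cfu,expected",
        [
            (5e7, "high"),
            (1.001e7, "high"),
            (1e7, "intermediate"),  # "more than 1e7" is strict
            (5e6, "intermediate"),
            (1e6, "intermediate"),
            (9.9e5, "low"),
            (1e3, "low"),
        ],
    )
    def test_class_boundaries(self, cfu, expected):
        assert classify_cfu(cfu) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_cfu(0.0)


class TestEnterocolitype:
    def test_human_exclusive_b2_is_e4(self):
        profile = _profile(p_b2=0.95, p_a=0.05)
        phenotype = build_phenotype(profile, 1e8, host_for_species("h", "human"))
        assert phenotype.enterocolitype == "E4"

    def test_human_dominant_nonexclusive_b2_is_e4(self):
        profile = _profile(p_b2=0.60, p_a=0.30, p_b1=0.10)
        phenotype = build_phenotype(profile, 1e8, host_for_species("h", "human"))
        assert phenotype.enterocolitype == "E4"

    def test_human_dominant_a_is_e5(self):
        profile = _profile(p_a=0.6, p_a1=0.3, p_b1=0.2, p_b2=0.1, p_d=0.1)
        phenotype = build_phenotype(profile, 1e8, host_for_species("h", "human"))
        assert phenotype.enterocolitype == "E5"

    def test_animal_dominant_b2_is_e1(self):
        profile = _profile(p_b2=0.7, p_a=0.2, p_d=0.1)
        phenotype = build_phenotype(profile, 3e5, host_for_species("w", "wild_rabbit"))
        assert phenotype.enterocolitype == "E1"

    def test_domesticated_sheep_dominant_b1_is_e2(self):
        profile = _profile(p_b1=0.60, p_a=0.25, p_d=0.15)
        phenotype = build_phenotype(profile, 5e6, host_for_species("s", "sheep"))
        assert phenotype.enterocolitype == "E2"

    def test_animal_dominant_a_is_e3(self):
        profile = _profile(p_a=0.55, p_b1=0.25, p_b2=0.1, p_d=0.1)
        phenotype = build_phenotype(profile, 5e7, host_for_species("p", "pig"))
        assert phenotype.enterocolitype == "E3"

    def test_no_dominant_group_is_unassigned(self):
        profile = _profile(p_a=0.4, p_b1=0.3, p_b2=0.2, p_d=0.1)
        phenotype = build_phenotype(profile, 5e7, host_for_species("p", "pig"))
        assert phenotype.enterocolitype == "unassigned"

    def test_dominant_d_animal_is_unassigned(self):
        profile = _profile(p_d=0.7, p_a=0.2, p_b1=0.1)
        phenotype = build_phenotype(profile, 5e7, host_for_species("p", "pig"))
        assert phenotype.enterocolitype == "unassigned"

    def test_diversity_class_needs_all_four_groups(self):
        profile = _profile(p_a=0.4, p_b1=0.3, p_b2=0.2, p_d=0.1)
        phenotype = build_phenotype(profile, 5e7, host_for_species("p", "pig"))
        assert phenotype.n_groups_detected == 4
        assert phenotype.diversity_class == "high"
        profile = _profile(p_a=0.5, p_b1=0.3, p_b2=0.2)  # D undetected
        phenotype = build_phenotype(profile, 5e7, host_for_species("p", "pig"))
        assert phenotype.n_groups_detected == 3
        assert phenotype.diversity_class == "low"


class TestIndicatorTable:
    def _pig_sample(self):
        # dominant A, intermediate B1, minor D, absent B2, 5e7 CFU/g
        profile = _profile(
            p_a=0.55, p_b1=0.30, p_d=0.05, p_b2=0.0,
            detected={"A": True, "B1": True, "D": True, "B2": False},
        )
        host = host_for_species("pig1", "pig")
        return build_phenotype(profile, 5e7, host), host

    def test_animal32_has_32_fixed_columns(self):
        phenotype, host = self._pig_sample()
        table = build_indicator_table([(phenotype, host)], "animal32")
        assert table.column_labels == ANIMAL32_COLUMNS
        assert len(table.column_labels) == 32

    def test_pig_example_encoding(self):
        phenotype, host = self._pig_sample()
        table = build_indicator_table([(phenotype, host)], "animal32")
        ones = {
            c for c, v in zip(table.column_labels, table.values[0]) if v == 1
        }
        assert ones == {
            "DA", "IB1", "MD", "AB2", "cfu_high", "diversity_low",
            "pig", "domesticated", "omnivorous",
        }

    def test_minor_a_contributes_no_indicator(self):
        # there is no "minor A" column: the A block stays all-zero
        profile = _profile(
            p_a=0.05, p_b1=0.55, p_b2=0.2, p_d=0.2,
            detected={"A": True, "B1": True, "B2": True, "D": True},
        )
        host = host_for_species("c", "cow")
        phenotype = build_phenotype(profile, 5e6, host)
        table = build_indicator_table([(phenotype, host)], "animal32")
        row = dict(zip(table.column_labels, table.values[0]))
        assert row["DA"] == 0 and row["IA"] == 0

    def test_exactly_one_per_exclusive_block(self, small_cohort):
        from colitype.pipeline import classify_samples, quantify_counts

        counts = [q for _, _, q in small_cohort]
        hosts = [h for h, _, _ in small_cohort]
        profiles = quantify_counts(counts, NoiseModel())
        _, _, table = classify_samples(profiles, hosts)
        frame = table.to_frame()
        blocks = [
            ["cfu_high", "cfu_intermediate", "cfu_low"],
            ["diversity_high", "diversity_low"],
            list(ANIMAL32_COLUMNS[19:28]),  # species
            ["wild", "domesticated"],
            ["herbivorous", "omnivorous"],
        ]
        for block in blocks:
            assert (frame[block].sum(axis=1) == 1).all(), block

    def test_humans_rejected_from_animal_table(self):
        profile = _profile(p_b2=0.95, p_a=0.05)
        host = host_for_species("h", "human")
        phenotype = build_phenotype(profile, 1e8, host)
        with pytest.raises(ValueError, match="animal hosts only"):
            build_indicator_table([(phenotype, host)], "animal32")

    def test_strain33_shape_on_packaged_panel(self):
        panel = load_b2_panel()
        table = build_indicator_table(panel, "strain33")
        assert table.values.shape == (43, 33)
        assert table.column_labels == STRAIN33_COLUMNS
        frame = table.to_frame()
        # origin and subgroup blocks are mutually exclusive
        assert (frame[list(STRAIN33_COLUMNS[:3])].sum(axis=1) == 1).all()
        assert (frame[list(STRAIN33_COLUMNS[3:12])].sum(axis=1) == 1).all()

    def test_strain33_from_reconstructed_groups(self):
        strains = (
            reconstruct_panel("human_exclusive")
            + reconstruct_panel("human_nonexclusive")
            + reconstruct_panel("animal")
        )
        table = build_indicator_table(strains, "strain33")
        assert table.values.shape == (43, 33)

    def test_drop_empty_columns(self):
        phenotype, host = self._pig_sample()
        table = build_indicator_table([(phenotype, host)], "animal32")
        pruned, dropped = drop_empty_columns(table)
        assert "DB1" in dropped
        assert pruned.values.shape[1] == 9  # the nine 1-columns remain
        assert (pruned.values == 1).all()

    def test_bad_variable_set_rejected(self):
        with pytest.raises(ValueError, match="variable_set"):
            build_indicator_table([], "animal31")


class TestRecovery:
    def test_zero_noise_recovery_smoke(self):
        """Zero-noise cohorts from every template are reassigned to their
        generating enterocolitype (small-n smoke check; the full 500-per-
        type check lives in the acceptance suite)."""
        from colitype.pipeline import classify_samples, quantify_counts

        noise = NoiseModel(log10_measurement_sd=0.0)
        cohort = simulate_cohort(default_templates(), 20, noise, seed=5)
        profiles = quantify_counts([q for _, _, q in cohort], noise)
        phenotypes, _, _ = classify_samples(
            profiles, [h for h, _, _ in cohort]
        )
        assignments = {p.sample_id: p.enterocolitype for p in phenotypes}
        hits = sum(
            1 for sid, e in assignments.items() if sid.startswith(e)
        )
        assert hits / len(assignments) >= 0.95
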