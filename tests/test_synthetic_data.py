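import numpy as np
import pytest

from bnpcp.profiles import apex_fraction, build_profiles
from bnpcp.synthetic_data import (
    EntitySpec,
    SubunitSpec,
    SyntheticTruth,
    default_truth,
    expected_intensity,
    simulate_table,
    truth_from_yaml,
    truth_to_yaml,
    write_fixture,
)


class TestDefaultTruth:
    def test_48_fractions(self):
        assert default_truth().n_fractions == 48

    def test_entity_apexes_inside_regression_window(self):
        truth = default_truth()
        for ent in truth.entities:
            assert 26 <= ent.apex_fraction <= 36

    def test_exactly_one_bait(self):
        truth = default_truth()
        assert sum(s.is_bait for s in truth.subunits) == 1

    def test_roster_composition(self):
        truth = default_truth()
        subs = [s for s in truth.subunits if not s.is_contaminant]
        flat = [s for s in subs if not s.is_bait and len(set(s.per_entity_ratio)) == 1
                and s.per_entity_ratio[0] > 0]
        enriched = [s for s in subs
                    if all(r > 0 for r in s.per_entity_ratio)
                    and s.per_entity_ratio[1] >= 2 * s.per_entity_ratio[0]]
        one_only = [s for s in subs if s.per_entity_ratio[0] > 0 and s.per_entity_ratio[1] == 0]
        two_only = [s for s in subs if s.per_entity_ratio[0] == 0 and s.per_entity_ratio[1] > 0]
        contaminants = [s for s in truth.subunits if s.is_contaminant]
        assert len(truth.entities) == 2
        assert len(flat) >= 6
        assert len(enriched) >= 2
        assert len(one_only) >= 1
        assert len(two_only) >= 1
        assert len(contaminants) >= 5


class TestValidation:
    def test_contaminant_with_signal_rejected(self):
        with pytest.raises(ValueError):
            SubunitSpec("X", "x", (1.0, 0.0), is_contaminant=True)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            EntitySpec("I", 10, 0.0, 1.0)

    def test_two_baits_rejected(self):
        ents = (EntitySpec("I", 5, 1.0, 1.0),)
        subs = (
            SubunitSpec("A", "a", (1.0,), is_bait=True),
            SubunitSpec("B", "b", (1.0,), is_bait=True),
        )
        with pytest.raises(ValueError):
            SyntheticTruth(n_fractions=10, entities=ents, subunits=subs)

    def test_invalid_replicate_rejected(self):
        with pytest.raises(ValueError):
            simulate_table(default_truth(), 3)


class TestSimulateTable:
    def test_zero_noise_equals_gaussian_mixture_exactly(self):
        truth = default_truth(noise_cv=0.0, dropout_rate=0.0)
        table = simulate_table(truth, 1)
        expected = expected_intensity(truth, 1)
        non_contam = [i for i, s in enumerate(truth.subunits) if not s.is_contaminant]
        np.testing.assert_array_equal(table.intensity[non_contam], expected[non_contam])

    def test_deterministic_under_seed(self):
        a = simulate_table(default_truth(seed=11), 1)
        b = simulate_table(default_truth(seed=11), 1)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.ibaq, b.ibaq)

    def test_replicates_differ(self):
        truth = default_truth(seed=11)
        a, b = simulate_table(truth, 1), simulate_table(truth, 2)
        assert not np.array_equal(a.intensity, b.intensity)

    def test_bait_apex_differs_by_replicate_shift(self):
        # oracle: argmax of the two noiseless bait rows
        truth = default_truth(noise_cv=0.0, dropout_rate=0.0, replicate_shift=2)
        bait_idx = [s.protein_id for s in truth.subunits].index(truth.bait.protein_id)
        apex1 = int(np.argmax(expected_intensity(truth, 1)[bait_idx])) + 1
        apex2 = int(np.argmax(expected_intensity(truth, 2)[bait_idx])) + 1
        assert apex2 - apex1 == truth.replicate_shift
        t1, t2 = simulate_table(truth, 1), simulate_table(truth, 2)
        a1 = apex_fraction(build_profiles(t1)[bait_idx])
        a2 = apex_fraction(build_profiles(t2)[bait_idx])
        assert a2 - a1 == truth.replicate_shift

    def test_ibaq_is_intensity_over_constant(self):
        truth = default_truth(seed=3)
        table = simulate_table(truth, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(table.ibaq > 0, table.intensity / table.ibaq, np.nan)
        for row in ratio:
            vals = row[np.isfinite(row)]
            if vals.size:
                assert np.allclose(vals, vals[0])
                assert vals[0] == pytest.approx(round(vals[0]))  # integer peptide count

    def test_contaminants_flagged_and_nonzero(self):
        table = simulate_table(default_truth(seed=2), 1)
        assert table.flag_contaminant.sum() == 6
        assert table.intensity[table.flag_contaminant].sum() > 0

    def test_dropout_zeroes_cells(self):
        t0 = simulate_table(default_truth(seed=4, dropout_rate=0.0), 1)
        t1 = simulate_table(default_truth(seed=4, dropout_rate=0.5), 1)
        assert (t1.intensity == 0).sum() > (t0.intensity == 0).sum()


class TestInvariantProperties:
    def test_zero_noise_profiles_recover_dominant_entity_apex(self):
        # brute force over all non-contaminant subunits
        truth = default_truth(noise_cv=0.0, dropout_rate=0.0)
        profiles = build_profiles(simulate_table(truth, 1))
        by_id = {p.protein_id: p for p in profiles}
        for sub in truth.subunits:
            if sub.is_contaminant:
                continue
            contributions = [
                r * e.bait_amount for r, e in zip(sub.per_entity_ratio, truth.entities)
            ]
            dominant = truth.entities[int(np.argmax(contributions))]
            assert apex_fraction(by_id[sub.protein_id]) == dominant.apex_fraction

    def test_flat_subunit_bait_ratio_constant_where_bait_nonzero(self):
        truth = default_truth(noise_cv=0.0, dropout_rate=0.0)
        expected = expected_intensity(truth, 1)
        ids = [s.protein_id for s in truth.subunits]
        bait_row = expected[ids.index("SYN0001")]
        flat_row = expected[ids.index("SYN0004")]  # per_entity_ratio (1.2, 1.2)
        mask = bait_row > 1e-300
        ratios = flat_row[mask] / bait_row[mask]
        np.testing.assert_allclose(ratios, 1.2, rtol=1e-9)


class TestFixture:
    def test_manifest_contains_two_tables(self, tmp_path):
        manifest = write_fixture(default_truth(seed=1), tmp_path)
        assert len(manifest["quant_tables"]) == 2

    def test_truth_round_trips(self, tmp_path):
        truth = default_truth(seed=9, noise_cv=0.15, dropout_rate=0.2, replicate_shift=1)
        path = truth_to_yaml(truth, tmp_path / "truth.yaml")
        assert truth_from_yaml(path) == truth

    def test_marker_spans_20_to_1200(self, tmp_path):
        from bnpcp.io_tables import read_marker_ladder

        manifest = write_fixture(default_truth(seed=1), tmp_path)
        ladder = read_marker_ladder(manifest["marker_ladder"])
        masses = [m for _, m in ladder]
        assert min(masses) == 20.0 and max(masses) == 1200.0

    def test_written_tables_parse_and_match(self, tmp_path):
        from bnpcp.io_tables import read_quant_table

        truth = default_truth(seed=6)
        manifest = write_fixture(truth, tmp_path)
        table = read_quant_table(manifest["quant_tables"][0])
        direct = simulate_table(truth, 1)
        assert table.protein_ids == direct.protein_ids
        np.testing.assert_allclose(table.intensity, direct.intensity, rtol=1e-9)

    def test_gene_lists_reflect_entity_membership(self, tmp_path):
        truth = default_truth(seed=1)
        manifest = write_fixture(truth, tmp_path)
        genes_II = set(
            (tmp_path / "genes_entity_II.txt").read_text().split()
        )
        assert "P2ONLY1" in genes_II
        assert "P1ONLY1" not in genes_II
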