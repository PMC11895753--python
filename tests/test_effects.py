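import numpy as np
import pandas as pd
import pytest

from paleopairs.cooccur import NullEngineConfig
from paleopairs.effects import (
    cohens_d,
    effect_table,
    magnitude_label,
    pair_differences,
    richness_preserving_null,
    summarize_types,
)
from paleopairs.occurrences import OccurrenceMatrix


def make_pairs(rows):
    return pd.DataFrame(
        rows, columns=["species_i", "species_j", "biozone", "classification"]
    )


@pytest.fixture
def small_inputs():
    traits = pd.DataFrame(
        {"species_id": ["a", "b", "c"], "ln_mass": [2.0, 5.0, 3.0]}
    )
    prefs = pd.DataFrame(
        {
            "species_id": ["a", "b", "c"],
            "pref1": [0.1, 0.1, 0.4],
            "pref2": [0.0, 0.2, 0.2],
            "n_sites": [2, 3, 1],
        }
    )
    pairs = make_pairs(
        [
            ("a", "b", "Cf3", "aggregated"),
            ("a", "c", "Cf3", "random"),
            ("b", "c", "Cf3", "random"),
        ]
    )
    return pairs, traits, prefs


class TestPairDifferences:
    def test_hand_computed_table(self, small_inputs):
        pairs, traits, prefs = small_inputs
        out = pair_differences(pairs, traits, prefs)
        ab = out[(out.species_i == "a") & (out.species_j == "b")].iloc[0]
        assert ab.d_mass == 3.0
        assert ab.d_pref1 == pytest.approx(0.0)
        assert ab.d_pref2 == pytest.approx(0.2)
        ac = out[(out.species_i == "a") & (out.species_j == "c")].iloc[0]
        assert ac.d_mass == 1.0 and ac.d_pref1 == pytest.approx(0.3)

    def test_pairs_missing_traits_dropped_not_fatal(self, small_inputs):
        pairs, traits, prefs = small_inputs
        out = pair_differences(pairs, traits.iloc[:2], prefs)
        assert len(out) == 1  # only (a, b) has both traits
        assert (out[["d_mass", "d_pref1", "d_pref2"]] >= 0).all().all()


class TestSummarizeTypes:
    def test_single_pair_cell(self, small_inputs):
        pairs, traits, prefs = small_inputs
        out = summarize_types(pair_differences(pairs, traits, prefs))
        cell = out[
            (out.classification == "aggregated") & (out.variable == "mass")
        ].iloc[0]
        assert cell.mean_diff == cell.median_diff == 3.0
        assert cell.n_pairs == 1

    def test_mean_vs_median(self):
        diffs = pd.DataFrame(
            {
                "species_i": list("aab"),
                "species_j": list("bcc"),
                "biozone": ["Cf3"] * 3,
                "classification": ["random"] * 3,
                "d_mass": [1.0, 2.0, 9.0],
                "d_pref1": [0.0] * 3,
                "d_pref2": [0.0] * 3,
            }
        )
        cell = summarize_types(diffs)
        mass = cell[cell.variable == "mass"].iloc[0]
        assert mass.mean_diff == 4.0 and mass.median_diff == 2.0

    def test_absent_classification_has_no_rows(self, small_inputs):
        pairs, traits, prefs = small_inputs
        out = summarize_types(pair_differences(pairs, traits, prefs))
        assert not (out.classification == "segregated").any()


class TestCohensD:
    def test_observed_equal_to_null_mean_is_zero_small(self):
        null = np.concatenate([np.full(20, 1.0), np.full(20, 3.0)])
        es = cohens_d(2.0, null)
        assert es.d == 0.0 and es.magnitude == "small"

    def test_point_eight_sd_above_is_large(self):
        rng = np.random.default_rng(0)
        null = rng.normal(10.0, 2.0, 500)
        obs = null.mean() + 0.8 * null.std(ddof=1)
        es = cohens_d(obs, null)
        assert es.d == pytest.approx(0.8)
        assert es.magnitude == "large"

    def test_minus_point_two_sd_is_small(self):
        rng = np.random.default_rng(1)
        null = rng.normal(0.0, 1.0, 100)
        obs = null.mean() - 0.2 * null.std(ddof=1)
        es = cohens_d(obs, null)
        assert es.d == pytest.approx(-0.2)
        assert es.magnitude == "small"

    def test_degenerate_and_short_nulls_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohens_d(1.0, np.full(50, 2.0))
        with pytest.raises(ValueError, match="30"):
            cohens_d(1.0, np.arange(10.0))

    def test_magnitude_boundaries(self):
        assert magnitude_label(0.2) == "small"
        assert magnitude_label(-0.8) == "large"
        assert magnitude_label(0.5) == "medium"


def _neutral_fixture(n_species=30, n_sites=12, seed=0):
    rng = np.random.default_rng(seed)
    mats = {}
    for b in ("Cf3", "Wa0", "Wa1_2"):
        cells = (rng.random((n_species, n_sites)) < 0.4).astype(np.int8)
        cells[cells.sum(axis=1) == 0, 0] = 1
        for j in np.nonzero(cells.sum(axis=0) == 0)[0]:
            cells[0, j] = 1
        mats[b] = OccurrenceMatrix(
            [f"sp{i:03d}" for i in range(n_species)],
            [f"{b}_s{j:02d}" for j in range(n_sites)],
            cells, b,
        ).validated()
    site_rows = []
    for b, m in mats.items():
        for s in m.site_ids:
            site_rows.append((s, f"f_{b}", 1.0, rng.normal(), rng.normal(), b))
    habitats = pd.DataFrame(
        site_rows,
        columns=["mammal_site_id", "matched_floral_site_id", "distance_km",
                 "NMDS1", "NMDS2", "biozone"],
    )
    traits = pd.DataFrame(
        {"species_id": [f"sp{i:03d}" for i in range(n_species)],
         "ln_mass": rng.normal(6, 2, n_species)}
    )
    return mats, habitats, traits


class TestRichnessPreservingNull:
    def test_per_site_richness_conserved_every_replicate(self):
        mats, habitats, traits = _neutral_fixture()
        from paleopairs.effects import _randomized_bins

        richness = {b: m.col_totals for b, m in mats.items()}
        rng = np.random.default_rng(3)
        z = _randomized_bins(richness, 30, rng)
        for b in mats:
            assert np.array_equal(z[b].sum(axis=0), richness[b])
            assert np.isin(z[b], (0, 1)).all()

    def test_same_seed_reproduces_null_means(self):
        mats, habitats, traits = _neutral_fixture()
        kw = dict(n_reps=4, inner=NullEngineConfig(n_null=60), seed=9)
        a = richness_preserving_null(mats, habitats, traits, **kw)
        b = richness_preserving_null(mats, habitats, traits, **kw)
        pd.testing.assert_frame_equal(a.rep_summaries, b.rep_summaries)

    def test_growing_n_reps_preserves_earlier_replicates(self):
        mats, habitats, traits = _neutral_fixture()
        small = richness_preserving_null(
            mats, habitats, traits, n_reps=3, inner=NullEngineConfig(n_null=60), seed=5
        )
        big = richness_preserving_null(
            mats, habitats, traits, n_reps=5, inner=NullEngineConfig(n_null=60), seed=5
        )
        pd.testing.assert_frame_equal(
            small.rep_summaries,
            big.rep_summaries[big.rep_summaries.rep < 3].reset_index(drop=True),
        )

    def test_pool_smaller_than_max_richness_raises(self):
        mats, habitats, traits = _neutral_fixture(n_species=5, n_sites=4)
        mats["Cf3"].cells[:, 0] = 1  # richness 5 == pool, fine
        traits = traits.iloc[:4]  # pool shrinks to 4 < richness 5
        with pytest.raises(ValueError, match="richness"):
            richness_preserving_null(
                mats, habitats, traits, n_reps=2, inner=NullEngineConfig(n_null=60)
            )


class TestEffectTable:
    def test_absent_cell_marked(self):
        mats, habitats, traits = _neutral_fixture()
        null = richness_preserving_null(
            mats, habitats, traits, n_reps=12, inner=NullEngineConfig(n_null=80), seed=2
        )
        # observed diffs with NO segregated pairs in Wa0
        rng = np.random.default_rng(0)
        rows = []
        for b in ("Cf3", "Wa0", "Wa1_2"):
            for cls in ("aggregated", "segregated", "random"):
                if b == "Wa0" and cls == "segregated":
                    continue
                for k in range(3):
                    rows.append(
                        (f"sp{k:03d}", f"sp{k + 1:03d}", b, cls,
                         abs(rng.normal()), abs(rng.normal()), abs(rng.normal()))
                    )
        diffs = pd.DataFrame(
            rows,
            columns=["species_i", "species_j", "biozone", "classification",
                     "d_mass", "d_pref1", "d_pref2"],
        )
        table = effect_table(diffs, null)
        assert len(table) == 27  # 3 bins x 3 types x 3 variables
        wa0_seg = table[
            (table.biozone == "Wa0") & (table.classification == "segregated")
        ]
        assert wa0_seg.absent.all()
        assert wa0_seg.magnitude.eq("absent").all()
        assert wa0_seg.d.isna().all()
        present = table[~table.absent]
        assert present.magnitude.isin(["small", "medium", "large"]).all()
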