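import numpy as np
import pytest

from petfusion import phantom
from petfusion.preprocess import to_suvr


@pytest.fixture(scope="module")
def desk_atlas():
    return phantom.build_parcellation((40, 48, 35), (4.0, 4.0, 4.0), seed=0)


class TestParcellation:
    def test_default_grid_has_twenty_regions(self):
        atlas = phantom.build_parcellation((79, 95, 69), (2.0, 2.0, 2.0), seed=0)
        present = set(np.unique(atlas.labels)) - {0}
        assert len(present) == 20
        assert sorted(atlas.registry) == list(range(1, 21))
        assert set(atlas.registry.values()) == set(phantom.REGION_NAMES)

    def test_every_region_at_least_64_voxels_on_default_grid(self):
        atlas = phantom.build_parcellation((79, 95, 69), (2.0, 2.0, 2.0), seed=3)
        sizes = [int((atlas.labels == l).sum()) for l in atlas.label_ids]
        assert min(sizes) >= 64

    def test_same_seed_reproducible(self):
        a = phantom.build_parcellation((40, 48, 35), (4, 4, 4), seed=7)
        b = phantom.build_parcellation((40, 48, 35), (4, 4, 4), seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            phantom.build_parcellation((20, 48, 35), (4, 4, 4), seed=0)


class TestSimulateSubject:
    def test_null_effect_recovers_baselines(self, desk_atlas):
        base = phantom.default_baseline()
        vols = [phantom.simulate_subject(desk_atlas, phantom.DiseaseEffect("HC"), base,
                                         seed=s, spacing=(4, 4, 4), fwhm_mm=0.0)
                for s in range(12)]
        for label, name in list(desk_atlas.registry.items())[::5]:
            m = desk_atlas.labels == label
            means = [v.data[m].mean() for v in vols]
            sd = np.std(means)
            assert abs(np.mean(means) - base[name]) < 3 * max(sd, 1e-3)

    def test_planted_factor_recovered_monte_carlo(self, desk_atlas):
        # mean putamen/whole-brain SUVR ratio over 50 subjects ~ 0.85 x HC ratio
        base = phantom.default_baseline()
        eff = phantom.default_effects()
        lab = [k for k, v in desk_atlas.registry.items() if v == "putamen"][0]
        m = desk_atlas.labels == lab

        def ratios(effect):
            out = []
            for s in range(50):
                v = phantom.simulate_subject(desk_atlas, effect, base, seed=900 + s,
                                             spacing=(4, 4, 4), fwhm_mm=0.0)
                out.append(to_suvr(v).data[m].mean())
            return np.asarray(out)

        r_msa, r_hc = ratios(eff["MSA"]), ratios(eff["HC"])
        se = (r_msa.std(ddof=1) + r_hc.std(ddof=1)) / np.sqrt(50) / r_hc.mean()
        assert r_msa.mean() / r_hc.mean() == pytest.approx(0.85, abs=2 * se + 1e-3)

    def test_seed_determinism(self, desk_atlas):
        base = phantom.default_baseline()
        eff = phantom.default_effects()["MSA"]
        a = phantom.simulate_subject(desk_atlas, eff, base, seed=5, spacing=(4, 4, 4))
        b = phantom.simulate_subject(desk_atlas, eff, base, seed=5, spacing=(4, 4, 4))
        assert np.array_equal(a.data, b.data)

    def test_no_effect_leakage_in_unaffected_regions(self, desk_atlas):
        # factor-1 regions show no class difference (t statistic within null bound)
        base = phantom.default_baseline()
        eff = phantom.default_effects()
        lab = [k for k, v in desk_atlas.registry.items() if v == "globus pallidus"][0]
        m = desk_atlas.labels == lab
        from scipy import stats

        def region_means(effect, seed0):
            return [phantom.simulate_subject(desk_atlas, effect, base, seed=seed0 + s,
                                             spacing=(4, 4, 4), fwhm_mm=0.0).data[m].mean()
                    for s in range(25)]

        t, _ = stats.ttest_ind(region_means(eff["MSA"], 100), region_means(eff["HC"], 500))
        assert abs(t) < 3.5  # ~99.9th percentile of the null at df=48

    def test_nonpositive_baseline_rejected(self, desk_atlas):
        base = phantom.default_baseline()
        base["putamen"] = 0.0
        with pytest.raises(ValueError):
            phantom.simulate_subject(desk_atlas, phantom.DiseaseEffect("HC"), base, seed=0)


class TestCohort:
    def test_counts_and_labels(self):
        spec = phantom.CohortSpec(counts={"IPD": 4, "MSA": 4, "PSP": 4},
                                  grid_shape=(40, 48, 35), spacing=(4, 4, 4), fwhm_mm=0.0)
        cohort = phantom.simulate_cohort(spec, seed=1)
        assert len(cohort.subjects) == 12
        labels = cohort.labels
        assert all(labels.count(c) == 4 for c in ("IPD", "MSA", "PSP"))
        assert len({s.subject_id for s in cohort.subjects}) == 12

    def test_cohort_seed_reproducible(self):
        spec = phantom.CohortSpec(counts={"IPD": 2, "MSA": 2, "PSP": 2},
                                  grid_shape=(40, 48, 35), spacing=(4, 4, 4), fwhm_mm=0.0)
        a = phantom.simulate_cohort(spec, seed=9)
        b = phantom.simulate_cohort(spec, seed=9)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.volume.data, sb.volume.data)

    def test_zero_count_rejected(self):
        spec = phantom.CohortSpec(counts={"IPD": 0, "MSA": 2})
        with pytest.raises(ValueError):
            phantom.simulate_cohort(spec, seed=0)

    def test_effect_factor_validation(self):
        with pytest.raises(ValueError):
            phantom.DiseaseEffect("MSA", {"putamen": -0.5})
        with pytest.raises(ValueError):
            phantom.DiseaseEffect("MSA", {"not a region": 0.9})


class TestPlantedTables:
    def test_shapes_and_standardization(self):
        ta, tb, ya, yb, inf = phantom.planted_tables(seed=0)
        assert ta.shape == (90, 50) and tb.shape == (90, 50)
        assert len(inf) == 5
        assert np.allclose(ta.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(ta.std(axis=0, ddof=0), 1, atol=1e-10)

    def test_informative_columns_carry_signal(self):
        from scipy import stats

        ta, _, ya, _, inf = phantom.planted_tables(seed=1)
        f_inf = [stats.f_oneway(*[ta[c][ya == k] for k in range(3)]).statistic for c in inf]
        f_noise = [stats.f_oneway(*[ta[c][ya == k] for k in range(3)]).statistic
                   for c in ta.columns[-5:]]
        assert min(f_inf) > max(f_noise)
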