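import numpy as np
import pytest

from idproteome import (
    ValidationError,
    ads,
    bootstrap_composition_test,
    generate_pools,
    generate_proteome,
    generate_tracks,
    normalized_pool_disorder,
    one_way_anova,
)
from idproteome.datatypes import CANONICAL_RESIDUES
from idproteome.synthetic import (
    PoolSpec,
    PredictorModel,
    SyntheticSpec,
    concentration_from_sd,
)


def spec(**kw):
    base = dict(
        group_sizes={"g1": 30, "g2": 30},
        length_range=(40, 60),
        predictor_models=[
            PredictorModel("p", {"g1": 0.40, "g2": 0.40}, ads_sd=0.1,
                           noise_sd=0.1, corr_length=5)
        ],
        pools=[],
        seed=7,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestProteome:
    def test_unbiased_composition_near_uniform(self):
        s = spec(group_sizes={"g1": 60, "g2": 1}, length_range=(180, 220))
        g = generate_proteome(s, "g1")  # ~12,000 residues
        seq = "".join(r.sequence for r in g)
        for residue in CANONICAL_RESIDUES:
            assert seq.count(residue) / len(seq) == pytest.approx(1 / 20, abs=0.01)

    def test_bias_recovered_end_to_end(self):
        biased = spec(composition_bias={"P": 3.0},
                      group_sizes={"g1": 60, "g2": 60},
                      length_range=(100, 140))
        q = generate_proteome(biased, "g1")
        b = generate_proteome(spec(group_sizes={"g1": 60, "g2": 60},
                                   length_range=(100, 140), seed=8), "g2")
        prof = bootstrap_composition_test(q, b, iterations=300, seed=5)
        row = prof.table.loc["P"]
        assert row["fractional_difference"] > 0
        assert row["significant"]

    def test_same_seed_identical_sequences(self):
        s1, s2 = spec(), spec()
        g1 = generate_proteome(s1, "g1")
        g2 = generate_proteome(s2, "g1")
        assert [r.sequence for r in g1] == [r.sequence for r in g2]
        assert g1.ids == g2.ids

    def test_groups_draw_independent_streams(self):
        s = spec()
        assert generate_proteome(s, "g1").records[0].sequence != \
               generate_proteome(s, "g2").records[0].sequence

    def test_unknown_group_raises(self):
        with pytest.raises(ValidationError):
            generate_proteome(spec(), "nope")


class TestTracks:
    def test_zero_noise_tracks_are_flat(self):
        s = spec(predictor_models=[
            PredictorModel("p", {"g1": 0.4, "g2": 0.4}, noise_sd=0.0)
        ])
        g = generate_proteome(s, "g1")
        for t in generate_tracks(g, s, "p"):
            assert np.ptp(t.scores) == 0.0

    def test_ads_recovery_at_moderate_noise(self):
        s = spec(group_sizes={"g1": 220, "g2": 1}, length_range=(150, 250),
                 predictor_models=[
                     PredictorModel("p", {"g1": 0.40, "g2": 0.40},
                                    ads_sd=0.10, noise_sd=0.15, corr_length=8)
                 ])
        g = generate_proteome(s, "g1")
        mean_ads = np.mean([ads(t) for t in generate_tracks(g, s, "p")])
        assert mean_ads == pytest.approx(0.40, abs=0.01)

    def test_separated_group_means_detected_by_anova(self):
        s = spec(group_sizes={"g1": 200, "g2": 200}, length_range=(60, 100),
                 predictor_models=[
                     PredictorModel("p", {"g1": 0.47, "g2": 0.39},
                                    ads_sd=0.12, noise_sd=0.1)
                 ])
        values = {
            name: [ads(t) for t in
                   generate_tracks(generate_proteome(s, name), s, "p")]
            for name in ("g1", "g2")
        }
        assert one_way_anova(values).p_value < 0.01

    def test_autocorrelation_increases_with_corr_length(self):
        def lag1(spec_obj):
            g = generate_proteome(spec_obj, "g1")
            tracks = generate_tracks(g, spec_obj, "p")
            cs = []
            for t in tracks:
                resid = t.scores - t.scores.mean()
                if resid.std() == 0:
                    continue
                cs.append(np.corrcoef(resid[:-1], resid[1:])[0, 1])
            return np.mean(cs)

        short = spec(group_sizes={"g1": 50, "g2": 1}, length_range=(120, 160),
                     predictor_models=[PredictorModel(
                         "p", {"g1": 0.45, "g2": 0.45}, noise_sd=0.15,
                         corr_length=1)])
        long = spec(group_sizes={"g1": 50, "g2": 1}, length_range=(120, 160),
                    predictor_models=[PredictorModel(
                        "p", {"g1": 0.45, "g2": 0.45}, noise_sd=0.15,
                        corr_length=15)])
        assert lag1(long) > lag1(short)

    def test_tracks_deterministic_under_seed(self):
        s = spec()
        g = generate_proteome(s, "g1")
        t1 = generate_tracks(g, s, "p")
        t2 = generate_tracks(g, s, "p")
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.scores, b.scores)

    def test_unknown_predictor_raises(self):
        s = spec()
        with pytest.raises(ValidationError):
            generate_tracks(generate_proteome(s, "g1"), s, "nope")


class TestPools:
    def test_degenerate_distribution_gives_unweighted_mean(self, rng):
        mdp = {f"P{i}": float(v) for i, v in enumerate(rng.uniform(0.2, 0.6, 40))}
        s = spec(pools=[PoolSpec("A", 39.0, lognormal_sigma=0.0)])
        (table,) = generate_pools(s, mdp)
        score = normalized_pool_disorder(table, mdp)
        assert score.score == pytest.approx(np.mean(list(mdp.values())), abs=1e-9)

    def test_concentrated_abundance_approaches_single_ads(self):
        mdp = {"P1": 0.9, "P2": 0.1}
        from idproteome import ExpressionTable

        t = ExpressionTable("A", 39, {"P1": 1e9, "P2": 1.0})
        assert normalized_pool_disorder(t, mdp).score == pytest.approx(0.9, abs=1e-6)

    def test_target_scores_recovered(self, rng):
        mdp = {f"P{i}": float(v) for i, v in enumerate(rng.uniform(0.05, 0.8, 120))}
        targets = (0.323, 0.310, 0.353, 0.310)
        s = spec(pools=[
            PoolSpec(pid, age, target_score=t)
            for pid, age, t in zip("ABCD", (38.5, 50.5, 60.0, 38.5), targets)
        ])
        tables = generate_pools(s, mdp)
        for table, target in zip(tables, targets):
            got = normalized_pool_disorder(table, mdp).score
            assert got == pytest.approx(target, abs=0.005)

    def test_unreachable_target_raises(self):
        mdp = {"P1": 0.6, "P2": 0.7}
        s = spec(pools=[PoolSpec("A", 39.0, target_score=0.2)])
        with pytest.raises(ValidationError, match="achievable"):
            generate_pools(s, mdp)

    def test_empty_pool_spec_raises(self):
        with pytest.raises(ValidationError, match="pools"):
            generate_pools(spec(), {"P1": 0.5})


class TestSpecValidation:
    def test_defaults_mirror_study_conditions(self):
        s = SyntheticSpec()
        assert s.group_sizes == {"younger_lens": 926, "older_lens": 261,
                                 "zonules": 279}
        assert len(s.predictor_models) == 6
        assert [p.pool_id for p in s.pools] == ["A", "B", "C", "D"]

    @pytest.mark.parametrize(
        "kw", [
            {"group_sizes": {"g": 0}},
            {"length_range": (10, 50)},
            {"composition_bias": {"P": -1.0}},
        ]
    )
    def test_invalid_specs_raise(self, kw):
        with pytest.raises(ValidationError):
            SyntheticSpec(**kw)

    def test_concentration_from_sd_roundtrip(self):
        kappa = concentration_from_sd(0.4, 0.15)
        var = 0.4 * 0.6 / (kappa + 1)
        assert np.sqrt(var) == pytest.approx(0.15)
        with pytest.raises(ValidationError):
            concentration_from_sd(0.5, 0.6)
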