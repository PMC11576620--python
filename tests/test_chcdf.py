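import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idproteome import (
    BoundaryConfig,
    DisorderTrack,
    ValidationError,
    assign_quadrant,
    baseline_disorder_track,
    cdf_curve,
    delta_cdf,
    delta_ch,
    mean_net_charge,
    mean_scaled_hydropathy,
)


@pytest.fixture(scope="module")
def config():
    return BoundaryConfig.default()


def track(scores, pid="P1"):
    return DisorderTrack(pid, "x", np.asarray(scores, dtype=float))


class TestHydropathy:
    def test_most_hydrophobic_homopolymer_is_one(self, config):
        # isoleucine tops the Kyte-Doolittle scale
        assert mean_scaled_hydropathy("I" * 20, config) == pytest.approx(1.0)

    def test_least_hydrophobic_homopolymer_is_zero(self, config):
        # arginine is the scale minimum
        assert mean_scaled_hydropathy("R" * 20, config) == pytest.approx(0.0)

    def test_windowed_mean_matches_two_loop_oracle(self, config, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 25))
        scale = config.hydropathy_scale
        lo, hi = min(scale.values()), max(scale.values())
        vals = [(scale[c] - lo) / (hi - lo) for c in seq]
        w = config.hydropathy_window
        windows = []
        for i in range(len(seq) - w + 1):
            windows.append(sum(vals[i:i + w]) / w)
        expected = sum(windows) / len(windows)
        assert mean_scaled_hydropathy(seq, config) == pytest.approx(expected, abs=1e-12)

    def test_sequence_shorter_than_window_raises(self, config):
        with pytest.raises(ValidationError, match="window"):
            mean_scaled_hydropathy("ACD", config)


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected", [("KKKK", 1.0), ("KDKD", 0.0), ("KKDAA", 0.2)]
    )
    def test_examples(self, seq, expected):
        assert mean_net_charge(seq) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            mean_net_charge("")


class TestDeltaCh:
    def test_charged_hydrophilic_is_disordered_side(self, config):
        assert delta_ch("E" * 30, config) > 0

    def test_hydrophobic_is_ordered_side(self, config):
        assert delta_ch("I" * 30, config) < 0

    def test_constructed_boundary_sequence_is_zero(self, config):
        # place the boundary exactly through this sequence's (H, R) point
        seq = "KKDAAILVFM" * 3
        h = mean_scaled_hydropathy(seq, config)
        r = mean_net_charge(seq)
        cfg = BoundaryConfig(
            ch_slope=config.ch_slope,
            ch_intercept=r - config.ch_slope * h,
            cdf_boundary_points=config.cdf_boundary_points,
            hydropathy_scale=config.hydropathy_scale,
            hydropathy_window=config.hydropathy_window,
        )
        assert delta_ch(seq, cfg) == pytest.approx(0.0, abs=1e-12)


class TestCdf:
    def test_two_point_curve(self):
        np.testing.assert_allclose(
            cdf_curve(track([0.2, 0.8]), [0.5, 1.0]), [0.5, 1.0]
        )

    def test_all_zero_scores_curve_is_one(self):
        np.testing.assert_allclose(
            cdf_curve(track([0.0] * 5), [0.1, 0.5, 0.9]), [1, 1, 1]
        )

    def test_counting_oracle(self, rng):
        s = rng.uniform(0, 1, 50)
        xs = np.linspace(0.1, 0.9, 7)
        expected = [sum(1 for v in s if v <= x) / 50 for x in xs]
        np.testing.assert_allclose(cdf_curve(track(s), xs), expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_curve_non_decreasing(self, seed):
        local = np.random.default_rng(seed)
        s = local.uniform(0, 1, local.integers(1, 80))
        curve = cdf_curve(track(s), np.linspace(0, 1, 9))
        assert (np.diff(curve) >= 0).all()
        assert curve[-1] == 1.0

    def test_delta_cdf_zero_when_curve_equals_boundary(self, config):
        # boundary rebuilt from an actual curve -> signed deviations vanish
        s = np.array([0.1, 0.2, 0.3, 0.6, 0.9])
        curve = cdf_curve(track(s), config.cdf_x)
        cfg = BoundaryConfig(
            ch_slope=config.ch_slope,
            ch_intercept=config.ch_intercept,
            cdf_boundary_points=tuple(zip(config.cdf_x, curve)),
            hydropathy_scale=config.hydropathy_scale,
        )
        assert delta_cdf(track(s), cfg) == pytest.approx(0.0, abs=1e-12)

    def test_all_ordered_track_closed_form(self, config):
        t = track([0.0] * 40)
        expected = float(np.mean(1.0 - config.cdf_y))
        assert delta_cdf(t, config) == pytest.approx(expected, abs=1e-12)

    def test_hand_averaged_signed_differences(self, config, rng):
        s = rng.uniform(0, 1, 60)
        curve = cdf_curve(track(s), config.cdf_x)
        expected = np.mean([c - b for c, b in zip(curve, config.cdf_y)])
        assert delta_cdf(track(s), config) == pytest.approx(expected, abs=1e-12)


class TestQuadrants:
    @pytest.mark.parametrize(
        "dch,dcdf,expected",
        [
            (-0.1, 0.1, "Q1"),
            (-0.1, -0.1, "Q2"),
            (0.1, -0.1, "Q3"),
            (0.1, 0.1, "Q4"),
            # ties: ΔCH >= 0 disordered side, ΔCDF >= 0 ordered side
            (0.0, 0.1, "Q4"),
            (0.0, -0.1, "Q3"),
            (-0.1, 0.0, "Q1"),
            (0.1, 0.0, "Q4"),
            (0.0, 0.0, "Q4"),
        ],
    )
    def test_sign_table_with_ties(self, dch, dcdf, expected):
        assert assign_quadrant(dch, dcdf) == expected

    def test_non_finite_raises(self):
        with pytest.raises(ValidationError):
            assign_quadrant(np.nan, 0.1)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        dch=st.floats(-5, 5), dcdf=st.floats(-5, 5),
        scale=st.floats(0.01, 100),
    )
    def test_invariant_under_positive_rescaling(self, dch, dcdf, scale):
        assert assign_quadrant(dch, dcdf) == assign_quadrant(
            dch * scale, dcdf * scale
        )


class TestBaselinePredictor:
    def test_charged_region_scores_disordered(self, config):
        t = baseline_disorder_track("E" * 30, config)
        assert (t.scores > 0.5).all()

    def test_hydrophobic_region_scores_ordered(self, config):
        t = baseline_disorder_track("I" * 30, config)
        assert (t.scores < 0.5).all()

    def test_chimera_transitions_across_junction(self, config):
        t = baseline_disorder_track("I" * 30 + "E" * 30, config)
        assert t.scores[:25].mean() < 0.5 < t.scores[35:].mean()
        # windowed oracle: transition region is monotone non-decreasing
        mid = t.scores[27:33]
        assert (np.diff(mid) >= -1e-12).all()

    def test_homopolymer_reversal_symmetry(self, config):
        fwd = baseline_disorder_track("K" * 21, config)
        rev = baseline_disorder_track("K" * 21, config)
        np.testing.assert_allclose(fwd.scores, rev.scores[::-1])

    def test_scores_inside_unit_interval(self, config, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
        t = baseline_disorder_track(seq, config)
        assert len(t) == 50
        assert (t.scores > 0).all() and (t.scores < 1).all()


def test_boundary_config_validation(config):
    with pytest.raises(ValidationError, match="increasing"):
        BoundaryConfig(
            ch_slope=1, ch_intercept=0,
            cdf_boundary_points=((0.5, 0.5), (0.5, 0.6)),
            hydropathy_scale=config.hydropathy_scale,
        )
    with pytest.raises(ValidationError, match="odd"):
        BoundaryConfig(
            ch_slope=1, ch_intercept=0,
            cdf_boundary_points=((0.2, 0.2), (0.8, 0.8)),
            hydropathy_scale=config.hydropathy_scale,
            hydropathy_window=4,
        )
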