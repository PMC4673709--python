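"""Quantile normalization, bottom-up segmentation and CNV calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from cnv_evodyn.profiles import ProbeProfile, read_probe_tsv, write_probe_tsv
from cnv_evodyn.segmentation import (
    CghCall,
    SegmentationParams,
    classify,
    quantile_normalize,
    segment,
    to_calls,
)


def make_profile(values, chrom="I", spacing=1000):
    values = np.asarray(values, dtype=float)
    pos = np.arange(1, values.size + 1) * spacing
    return ProbeProfile({chrom: (pos, values)})


class TestQuantileNormalize:
    def test_single_profile_is_identity(self):
        profile = make_profile([0.3, -0.1, 0.7])
        (out,) = quantile_normalize([profile])
        assert out == profile

    def test_hand_computed_mean_order_statistics(self):
        a = make_profile([1.0, 2.0, 3.0])
        b = make_profile([2.0, 4.0, 6.0])
        out_a, out_b = quantile_normalize([a, b])
        np.testing.assert_allclose(out_a.ratios("I"), [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out_b.ratios("I"), [1.5, 3.0, 4.5])

    def test_mismatched_probe_sets_rejected(self):
        a = make_profile([1.0, 2.0, 3.0])
        b = make_profile([1.0, 2.0, 3.0], spacing=500)
        with pytest.raises(ValueError, match="identical probe set"):
            quantile_normalize([a, b])

    @given(
        values=st.lists(
            st.floats(-2, 2, allow_nan=False), min_size=3, max_size=20
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permuted_profiles_equalize(self, values, seed):
        """Profiles that permute the same values end up identical multisets."""
        rng = np.random.default_rng(seed)
        a = np.array(values)
        b = rng.permutation(a)
        out_a, out_b = quantile_normalize([make_profile(a), make_profile(b)])
        np.testing.assert_allclose(
            np.sort(out_a.ratios("I")), np.sort(out_b.ratios("I"))
        )


class TestSegment:
    def test_constant_profile_is_one_segment(self):
        profile = make_profile(np.full(25, 0.4))
        segs = segment(profile, SegmentationParams())
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index) == (0, 24)

    def test_noiseless_step_found_exactly(self):
        profile = make_profile(np.r_[np.zeros(20), np.ones(20)])
        segs = segment(profile, SegmentationParams(p_merge=0.01))
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 19), (20, 39)]

    def test_partition_property(self, rng):
        values = rng.normal(0, 0.25, 60)
        values[20:40] += 1.0
        segs = segment(make_profile(values), SegmentationParams())
        covered = []
        for s in segs:
            covered.extend(range(s.start_index, s.end_index + 1))
        assert covered == list(range(60))

    def test_stopping_condition_matches_brute_force(self, rng):
        """No adjacent surviving pair may reach the merge threshold.

        Verified against independent Welch t-tests (scipy) on every
        adjacent pair of the final segmentation, for small profiles.
        """
        params = SegmentationParams(p_merge=0.05)
        for trial in range(20):
            values = rng.normal(0, 0.3, int(rng.integers(4, 13)))
            values[values.size // 2 :] += rng.choice([0.0, 1.0])
            profile = make_profile(values)
            segs = segment(profile, params)
            for left, right in zip(segs, segs[1:]):
                a = values[left.start_index : left.end_index + 1]
                b = values[right.start_index : right.end_index + 1]
                if a.size > 1 and b.size > 1:
                    p = sstats.ttest_ind(a, b, equal_var=False).pvalue
                    assert p < params.p_merge

    def test_stricter_threshold_never_decreases_segments(self, rng):
        values = rng.normal(0, 0.3, 40)
        values[15:30] += 0.8
        profile = make_profile(values)
        counts = [
            len(segment(profile, SegmentationParams(p_merge=p)))
            for p in (1e-6, 1e-4, 1e-2, 0.5)
        ]
        assert counts == sorted(counts)


class TestClassify:
    def test_zero_mean_segment_is_neutral(self, rng):
        profile = make_profile(rng.normal(0, 0.2, 30))
        params = SegmentationParams()
        segs = classify(segment(profile, params), profile, params)
        assert all(s.label == "neutral" for s in segs)

    def test_strong_gain_is_amplified(self, rng):
        values = rng.normal(1.0, 0.2, 50)
        profile = make_profile(values)
        params = SegmentationParams(m_min=0.2, p_class=1e-3)
        segs = classify(segment(profile, params), profile, params)
        # noise may split the region, but every classifiable piece is a gain
        assert all(
            s.label == "amplified" for s in segs if s.n_probes >= params.min_probes
        )
        assert sum(s.n_probes for s in segs if s.label == "amplified") >= 45

    def test_min_probe_filter_blocks_short_segments(self):
        profile = make_profile([0.0] * 10 + [1.5, 1.6] + [0.0] * 10)
        params = SegmentationParams(min_probes=3, p_merge=1e-4)
        segs = classify(segment(profile, params), profile, params)
        assert all(
            s.label == "neutral" for s in segs if s.n_probes < 3
        )
        assert not any(s.label == "amplified" and s.n_probes < 3 for s in segs)


class TestToCalls:
    def _amplified_profile(self, mean, rng, n=40):
        values = np.r_[rng.normal(0, 0.05, 30), rng.normal(mean, 0.05, n),
                       rng.normal(0, 0.05, 30)]
        return make_profile(values)

    def test_copy_number_and_frequency_from_mean(self, rng):
        profile = self._amplified_profile(1.0, rng)
        params = SegmentationParams()
        segs = classify(segment(profile, params), profile, params)
        (call,) = [c for c in to_calls(segs, profile) if c.kind == "duplication"]
        assert call.copy_per_haploid == pytest.approx(2.0, abs=0.15)
        assert call.frequency == pytest.approx(1.0, abs=0.05)

    def test_outer_interval_extends_to_flanking_probes(self, rng):
        profile = self._amplified_profile(1.0, rng)
        params = SegmentationParams()
        segs = classify(segment(profile, params), profile, params)
        (call,) = [c for c in to_calls(segs, profile) if c.kind == "duplication"]
        pos = profile.positions("I")
        assert call.outer_start == pos[30 - 1] + 1
        assert call.outer_end == pos[30 + 40] - 1
        assert call.outer_start <= call.inner_start <= call.inner_end <= call.outer_end

    def test_conversion_arithmetic(self):
        # frequency = 2^mean - 1 for amplifications, 1 - 2^mean for deletions
        from cnv_evodyn.segmentation import Segment

        profile = make_profile([0.496] * 5 + [-4.0] * 5)
        segs = [
            Segment("I", 0, 4, 5, 0.496, 0.0, label="amplified"),
            Segment("I", 5, 9, 5, -4.0, 0.0, label="deleted"),
        ]
        dup, dele = to_calls(segs, profile)
        assert dup.copy_per_haploid == pytest.approx(1.41, abs=0.005)
        assert dup.frequency == pytest.approx(0.41, abs=0.005)
        assert dele.copy_per_haploid == pytest.approx(0.0625)
        assert dele.frequency == pytest.approx(0.9375)

    def test_frequency_clipped_to_unit_interval(self):
        from cnv_evodyn.segmentation import Segment

        profile = make_profile([1.2] * 5)
        (call,) = to_calls([Segment("I", 0, 4, 5, 1.2, 0.0, "amplified")], profile)
        assert call.frequency == 1.0  # 2^1.2 - 1 = 1.30 clipped


class TestEndToEndRecovery:
    @pytest.mark.parametrize("q", [0.25, 0.5, 1.0])
    def test_frequency_recovery_under_noise(self, q):
        """Median |q_hat - q| < 0.1 across seeded noisy simulations."""
        from cnv_evodyn.synthetic import (
            CnvSpec,
            NoiseModel,
            PopulationCnvConfig,
            make_genome,
            simulate_acgh,
        )

        genome = make_genome(1, 120_000, 1_000, 0, seed=0)
        config = PopulationCnvConfig(
            (CnvSpec("I", 40_001, 80_000, "duplication", q),)
        )
        params = SegmentationParams()
        errors = []
        for seed in range(100):
            profile = simulate_acgh(
                genome, config, NoiseModel(probe_sd=0.25, seed=seed)
            )
            segs = classify(segment(profile, params), profile, params)
            calls = [c for c in to_calls(segs, profile) if c.kind == "duplication"]
            matched = [
                c for c in calls if c.inner_start <= 80_000 and c.inner_end >= 40_001
            ]
            errors.append(
                abs(matched[0].frequency - q) if matched else 1.0
            )
        assert np.median(errors) < 0.1


def test_probe_tsv_round_trip(tmp_path, rng):
    profile = make_profile(rng.normal(0, 0.3, 20))
    path = tmp_path / "probes.tsv"
    write_probe_tsv(profile, path)
    assert read_probe_tsv(path) == profile
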