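import numpy as np
import pytest
from scipy.stats import chisquare

from mtmask.io_core import RegionAssignment
from mtmask.masking import (
    MaskParams,
    MaskScheme,
    TRAINING_SCHEMES,
    apply_causal_mask,
    apply_inter_region_mask,
    apply_intra_region_mask,
    apply_neuron_mask,
    apply_scheme,
    apply_temporal_mask,
    mask_input,
    sample_scheme,
)

PARAMS = MaskParams()


def _regions(sizes: dict[str, int]) -> RegionAssignment:
    return RegionAssignment([lab for lab, n in sizes.items() for _ in range(n)])


class TestSampleScheme:
    def test_uniform_over_training_schemes(self):
        rng = np.random.default_rng(0)
        draws = [sample_scheme(rng) for _ in range(4000)]
        counts = [sum(d is s for d in draws) for s in TRAINING_SCHEMES]
        assert all(900 <= c <= 1100 for c in counts)
        assert chisquare(counts).pvalue > 0.01

    def test_seeded_rng_reproducible(self):
        a = [sample_scheme(np.random.default_rng(5)) for _ in range(1)]
        b = [sample_scheme(np.random.default_rng(5)) for _ in range(1)]
        assert a == b

    def test_temporal_never_sampled(self):
        rng = np.random.default_rng(1)
        assert all(sample_scheme(rng) is not MaskScheme.TEMPORAL for _ in range(1000))


class TestNeuronMask:
    def test_ceiling_arithmetic(self):
        m = apply_neuron_mask((5, 4), MaskParams(neuron_mask_ratio=0.25),
                              np.random.default_rng(0))
        masked_cols = (~m.context_mask).all(axis=0)
        assert masked_cols.sum() == 1

    def test_masked_column_structure(self):
        m = apply_neuron_mask((5, 4), MaskParams(neuron_mask_ratio=0.25),
                              np.random.default_rng(0))
        col = np.flatnonzero(m.target_mask.any(axis=0))
        assert m.target_mask[:, col].all()
        assert not m.context_mask[:, col].any()
        others = np.setdiff1d(np.arange(4), col)
        assert m.context_mask[:, others].all()
        assert not m.target_mask[:, others].any()

    def test_inclusion_frequency_matches_expectation(self):
        rng = np.random.default_rng(0)
        hits = np.zeros(10)
        n_draws = 10_000
        for _ in range(n_draws):
            m = apply_neuron_mask((1, 10), MaskParams(neuron_mask_ratio=0.3), rng)
            hits += m.target_mask[0]
        # each neuron in the 3-subset with p = 0.3; binomial 4-sigma band
        sd = np.sqrt(n_draws * 0.3 * 0.7)
        assert np.all(np.abs(hits - 3000) < 4 * sd)

    def test_ratio_rounding_to_all_neurons_rejected(self):
        with pytest.raises(ValueError):
            apply_neuron_mask((5, 2), MaskParams(neuron_mask_ratio=0.9),
                              np.random.default_rng(0))


class TestCausalMask:
    def test_default_horizon_is_last_tenth(self):
        m = apply_causal_mask((200, 3), PARAMS)
        assert (~m.context_mask[:, 0]).sum() == 20
        assert m.target_mask[180:].all() and not m.target_mask[:180].any()

    def test_ceiling_with_short_trials(self):
        m = apply_causal_mask((10, 3), PARAMS)
        assert m.target_mask[9:].all() and not m.target_mask[:9].any()

    def test_no_neuron_dependence(self):
        m = apply_causal_mask((20, 7), PARAMS)
        assert (m.context_mask == m.context_mask[:, :1]).all()
        assert (m.target_mask == m.target_mask[:, :1]).all()


class TestIntraRegionMask:
    def test_eligibility_filter(self):
        regions = _regions({"A": 3, "B": 5})
        params = MaskParams(min_region_size=4)
        for seed in range(20):
            m = apply_intra_region_mask((4, 8), regions, params,
                                        np.random.default_rng(seed))
            assert m.chosen_region == "B"

    def test_structure_within_chosen_region(self):
        regions = _regions({"A": 3, "B": 5})
        m = apply_intra_region_mask((4, 8), regions, MaskParams(min_region_size=4,
                                    region_mask_ratio=0.4), np.random.default_rng(0))
        b = regions.membership("B")
        assert m.target_mask[:, b].any(axis=0).sum() == 2  # ceil(0.4 * 5)
        # out-of-region neurons invisible and unscored
        assert not m.context_mask[:, ~b].any()
        assert not m.target_mask[:, ~b].any()
        # same-region unmasked neurons are context
        ctx_cols = m.context_mask.all(axis=0)
        assert ctx_cols[b].sum() == 3

    def test_region_choice_uniform(self):
        regions = _regions({"A": 6, "B": 6})
        rng = np.random.default_rng(0)
        picks = [apply_intra_region_mask((2, 12), regions, PARAMS, rng).chosen_region
                 for _ in range(10_000)]
        nA = picks.count("A")
        assert abs(nA - 5000) < 4 * np.sqrt(10_000 * 0.25)

    def test_no_eligible_region_rejected(self):
        with pytest.raises(ValueError):
            apply_intra_region_mask((4, 4), _regions({"A": 2, "B": 2}), PARAMS,
                                    np.random.default_rng(0))


class TestInterRegionMask:
    def test_whole_region_hidden_and_scored(self):
        regions = _regions({"A": 5, "B": 5})
        m = apply_inter_region_mask((4, 10), regions, PARAMS, np.random.default_rng(0))
        chosen = regions.membership(m.chosen_region)
        assert m.target_mask[:, chosen].all()
        assert not m.context_mask[:, chosen].any()
        assert m.context_mask[:, ~chosen].all()
        assert not m.target_mask[:, ~chosen].any()

    def test_disjointness(self):
        regions = _regions({"A": 5, "B": 5})
        for seed in range(50):
            m = apply_inter_region_mask((3, 10), regions, PARAMS,
                                        np.random.default_rng(seed))
            assert not (m.context_mask & m.target_mask).any()

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            apply_inter_region_mask((4, 6), _regions({"A": 6}), PARAMS,
                                    np.random.default_rng(0))

    def test_region_choice_uniform(self):
        regions = _regions({"A": 5, "B": 5})
        rng = np.random.default_rng(3)
        picks = [apply_inter_region_mask((2, 10), regions, PARAMS, rng).chosen_region
                 for _ in range(10_000)]
        assert abs(picks.count("A") - 5000) < 4 * np.sqrt(10_000 * 0.25)


class TestTemporalMask:
    def test_bin_arithmetic(self):
        m = apply_temporal_mask((10, 4), PARAMS, np.random.default_rng(0))
        masked_rows = (~m.context_mask).all(axis=1)
        assert masked_rows.sum() == 3

    def test_rows_uniform_over_bins(self):
        rng = np.random.default_rng(0)
        hits = np.zeros(10)
        for _ in range(10_000):
            m = apply_temporal_mask((10, 2), PARAMS, rng)
            hits += m.target_mask[:, 0]
        assert np.all(np.abs(hits - 3000) < 4 * np.sqrt(10_000 * 0.21))

    def test_no_neuron_selectivity(self):
        for seed in range(20):
            m = apply_temporal_mask((10, 5), PARAMS, np.random.default_rng(seed))
            assert (m.context_mask == m.context_mask[:, :1]).all()


class TestSchemeInvariants:
    @pytest.mark.parametrize("scheme", list(MaskScheme))
    def test_disjoint_and_nonempty_over_random_draws(self, scheme):
        rng = np.random.default_rng(99)
        regions = _regions({"A": 7, "B": 5, "C": 6})
        for _ in range(100):
            T = int(rng.integers(5, 40))
            m = apply_scheme(scheme, (T, 18), regions, PARAMS, rng)
            assert not (m.context_mask & m.target_mask).any()
            assert m.target_mask.any()
            assert m.context_mask.any()


class TestMaskInput:
    def test_all_visible_is_identity(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(3, 5, 4))
        m = apply_neuron_mask((5, 4), MaskParams(neuron_mask_ratio=0.25),
                              np.random.default_rng(0))
        full = np.ones_like(m.context_mask)
        m.context_mask = full
        m.target_mask = np.zeros_like(full)
        m.target_mask[0, 0] = True
        np.testing.assert_array_equal(mask_input(counts, m), counts)

    def test_hidden_column_zeroed(self):
        counts = np.ones((2, 4, 3), dtype=int)
        m = apply_neuron_mask((4, 3), MaskParams(neuron_mask_ratio=0.34),
                              np.random.default_rng(1))
        out = mask_input(counts, m)
        hidden = ~m.context_mask[0]
        assert (out[:, :, hidden].sum()) == 0
        assert (out[:, :, ~hidden] == 1).all()

    def test_no_aliasing(self):
        counts = np.ones((1, 4, 3), dtype=int)
        m = apply_neuron_mask((4, 3), MaskParams(neuron_mask_ratio=0.34),
                              np.random.default_rng(1))
        out = mask_input(counts, m)
        out[...] = 99
        assert counts.max() == 1

    def test_intra_region_leaks_nothing_across_regions(self):
        regions = _regions({"A": 4, "B": 6})
        params = MaskParams(min_region_size=4)
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(2, 6, 10))
        m = apply_intra_region_mask((6, 10), regions, params, np.random.default_rng(2))
        out1 = mask_input(counts, m)
        perturbed = counts.copy()
        outside = ~regions.membership(m.chosen_region)
        perturbed[:, :, outside] += 17
        out2 = mask_input(perturbed, m)
        np.testing.assert_array_equal(out1, out2)

    def test_shape_mismatch_rejected(self):
        m = apply_causal_mask((10, 3), PARAMS)
        with pytest.raises(ValueError):
            mask_input(np.zeros((2, 9, 3)), m)
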