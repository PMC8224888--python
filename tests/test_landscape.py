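"""Boltzmann conversions, binding scores, projections, convergence, Welch test.

Each weighted-sum operation is checked against an independently coded
explicit-loop oracle on random fields.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripletabf import (
    CheckpointSeries,
    FreeEnergyField,
    GridSpec,
    ProbabilityField,
    RegionSpec,
    average_probability,
    binding_scores,
    convergence_series,
    default_grid,
    free_energy_from_probability,
    probability_from_free_energy,
    project,
    welch_t_test,
)
from conftest import make_probability


def tiny_grid(n=2):
    return GridSpec((4.0,) * 3, (4.0 + 0.5 * n,) * 3, 0.5)


# ---------------------------------------------------------------- oracles

def boltzmann_loop(g_values, mask):
    """Direct exp/normalize loop."""
    out = np.zeros_like(g_values)
    z = 0.0
    for idx in np.ndindex(g_values.shape):
        if mask[idx]:
            z += math.exp(-g_values[idx])
    for idx in np.ndindex(g_values.shape):
        if mask[idx]:
            out[idx] = math.exp(-g_values[idx]) / z
    return out


def scores_loop(g, p, lo_b, hi_b, lo_u, hi_u, grid):
    """Triple-sum of the probability-weighted region means."""
    sums = {"b": [0.0, 0.0], "u": [0.0, 0.0]}
    for idx in np.ndindex(grid.shape):
        c = [grid.centers(a)[idx[a]] for a in range(3)]
        if not (g.mask[idx] and p.mask[idx]):
            continue
        if all(lo_b <= x <= hi_b for x in c):
            sums["b"][0] += g.values[idx] * p.values[idx]
            sums["b"][1] += p.values[idx]
        if all(lo_u <= x <= hi_u for x in c):
            sums["u"][0] += g.values[idx] * p.values[idx]
            sums["u"][1] += p.values[idx]
    return sums["b"][0] / sums["b"][1], sums["u"][0] / sums["u"][1]


def project_loop(g, p, drop_axis):
    """Double-loop marginalization of G over one axis."""
    shape2 = tuple(n for a, n in enumerate(g.values.shape) if a != drop_axis)
    g2 = np.zeros(shape2)
    m2 = np.zeros(shape2, bool)
    for idx2 in np.ndindex(shape2):
        num = den = 0.0
        for k in range(g.values.shape[drop_axis]):
            idx = list(idx2)
            idx.insert(drop_axis, k)
            idx = tuple(idx)
            if p.mask[idx] and g.mask[idx]:
                num += g.values[idx] * p.values[idx]
            if p.mask[idx]:
                den += p.values[idx]
        if den > 0:
            g2[idx2] = num / den
            m2[idx2] = True
    return g2, m2


# ------------------------------------------------- probability <-> energy

class TestBoltzmannConversions:
    def test_uniform_energy_gives_uniform_probability(self, grid):
        g = FreeEnergyField.from_values(grid, np.zeros(grid.shape))
        p = probability_from_free_energy(g)
        assert np.allclose(p.values, 1.0 / grid.n_bins, atol=1e-15)

    def test_two_bin_closed_form(self):
        grid = tiny_grid(2)
        mask = np.zeros(grid.shape, bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        v = np.zeros(grid.shape)
        v[1, 0, 0] = math.log(2)
        g = FreeEnergyField(grid, v, mask)
        p = probability_from_free_energy(g)
        assert p.values[0, 0, 0] == pytest.approx(2 / 3, abs=1e-15)
        assert p.values[1, 0, 0] == pytest.approx(1 / 3, abs=1e-15)
        back = free_energy_from_probability(p)
        assert back.values[0, 0, 0] == pytest.approx(0.0, abs=1e-14)
        assert back.values[1, 0, 0] == pytest.approx(math.log(2), abs=1e-14)

    def test_matches_bruteforce_loop(self, random_energy_field):
        p = probability_from_free_energy(random_energy_field)
        expect = boltzmann_loop(
            random_energy_field.values, random_energy_field.mask
        )
        assert np.abs(p.values - expect).max() < 1e-14

    def test_normalization_with_partial_mask(self, grid, rng):
        p = make_probability(grid, rng, sparsity=0.5)
        assert abs(p.values[p.mask].sum() - 1.0) < 1e-12
        assert np.all(p.values[~p.mask] == 0.0)

    def test_zero_probability_bins_become_unmasked(self, grid):
        w = np.ones(grid.shape)
        w[0, 0, 0] = 0.0
        p = ProbabilityField.from_weights(grid, w)
        g = free_energy_from_probability(p)
        assert not g.mask[0, 0, 0]
        assert np.isfinite(g.values).all()

    def test_uniform_probability_gives_zero_energy(self, grid):
        p = ProbabilityField.from_weights(grid, np.ones(grid.shape))
        g = free_energy_from_probability(p)
        assert np.abs(g.values).max() < 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_recovers_min_shifted_energy(self, seed):
        rng = np.random.default_rng(seed)
        grid = default_grid()
        raw = rng.uniform(-5, 15, grid.shape)
        g = FreeEnergyField.from_values(grid, raw)
        back = free_energy_from_probability(probability_from_free_energy(g))
        assert np.abs(back.values - (raw - raw.min())).max() < 1e-10

    def test_empty_mask_errors(self, grid):
        v = np.zeros(grid.shape)
        with pytest.raises(ValueError):
            FreeEnergyField(grid, v, np.zeros(grid.shape, bool))


# ------------------------------------------------------------ averaging

class TestAverageProbability:
    def test_single_and_identical_trials_are_identity(self, grid, rng):
        p = make_probability(grid, rng)
        for trials in ([p], [p, p]):
            avg = average_probability(trials)
            assert np.abs(avg.values - p.values).max() < 1e-14

    def test_five_random_trials_match_loop_mean(self, grid, rng):
        trials = [make_probability(grid, rng, sparsity=0.3) for _ in range(5)]
        avg = average_probability(trials)
        expect = np.zeros(grid.shape)
        for idx in np.ndindex(grid.shape):
            expect[idx] = sum(t.values[idx] for t in trials) / 5.0
        expect /= expect.sum()
        assert np.abs(avg.values - expect).max() < 1e-14
        # masked iff visited in >= 1 trial
        union = np.any([t.mask for t in trials], axis=0)
        assert np.array_equal(avg.mask, union)

    def test_mismatched_grids_rejected(self, grid, rng):
        other = GridSpec((4.0,) * 3, (9.0,) * 3, 1.0)
        p1 = make_probability(grid, rng)
        p2 = ProbabilityField.from_weights(other, np.ones(other.shape))
        with pytest.raises(ValueError):
            average_probability([p1, p2])


# --------------------------------------------------------- binding scores

class TestBindingScores:
    def test_piecewise_constant_energy(self, grid, rng):
        g0 = 2.5
        bound = RegionSpec(4.0, 6.0).member_mask(grid)
        unbound = RegionSpec(7.0, 9.0).member_mask(grid)
        v = np.zeros(grid.shape)
        v[unbound] = g0
        g = FreeEnergyField.from_values(grid, v)
        p = make_probability(grid, rng)
        sc = binding_scores(g, p)
        assert sc.g_bound == pytest.approx(0.0, abs=1e-14)
        assert sc.g_unbound == pytest.approx(g0, abs=1e-12)
        assert sc.dg_binding == pytest.approx(-g0, abs=1e-12)

    def test_symmetric_landscape_has_zero_gap(self, grid):
        # G and P symmetric under reflection of every axis, which maps the
        # bound region onto the unbound region
        v = np.zeros(grid.shape)
        for idx in np.ndindex(grid.shape):
            v[idx] = sum(abs(grid.centers(a)[idx[a]] - 6.5) for a in range(3))
        g = FreeEnergyField.from_values(grid, v)
        p = probability_from_free_energy(g)
        sc = binding_scores(g, p)
        assert sc.dg_binding == pytest.approx(0.0, abs=1e-12)

    def test_matches_triple_sum_oracle(self, random_energy_field,
                                       random_probability_field):
        g, p = random_energy_field, random_probability_field
        sc = binding_scores(g, p)
        gb, gu = scores_loop(g, p, 4.0, 6.0, 7.0, 9.0, g.grid)
        assert sc.g_bound == pytest.approx(gb, abs=1e-12)
        assert sc.g_unbound == pytest.approx(gu, abs=1e-12)
        assert sc.dg_binding == sc.g_bound - sc.g_unbound  # exact identity

    def test_constant_shift_leaves_gap_unchanged(self, grid, rng):
        raw = rng.uniform(0, 5, grid.shape)
        p = make_probability(grid, rng)
        g1 = FreeEnergyField.from_values(grid, raw)
        g2 = FreeEnergyField.from_values(grid, raw + 3.7)
        assert binding_scores(g2, p).dg_binding == pytest.approx(
            binding_scores(g1, p).dg_binding, abs=1e-12
        )

    def test_unsampled_region_errors(self, grid):
        w = np.zeros(grid.shape)
        w[0, 0, 0] = 1.0  # only the bound corner is sampled
        p = ProbabilityField.from_weights(grid, w)
        g = FreeEnergyField.from_values(grid, np.zeros(grid.shape),
                                        p.mask.copy())
        with pytest.raises(ValueError, match="region unsampled"):
            binding_scores(g, p)


# ------------------------------------------------------------ projection

class TestProjection:
    def test_invalid_axis_pair_rejected(self, random_energy_field,
                                        random_probability_field):
        with pytest.raises(ValueError):
            project(random_energy_field, random_probability_field, (2, 1))

    def test_single_bin_dropped_axis_is_a_slice(self, rng):
        grid = GridSpec((4.0, 4.0, 4.0), (9.0, 9.0, 4.5), 0.5)
        raw = rng.uniform(0, 4, grid.shape)
        g = FreeEnergyField.from_values(grid, raw)
        p = probability_from_free_energy(g)
        g2, _ = project(g, p, (1, 2))
        sl = g.values[:, :, 0]
        assert np.abs(g2.values - (sl - sl.min())).max() < 1e-12

    def test_separable_landscape_projects_additively(self, grid, rng):
        parts = [rng.uniform(0, 3, 10) for _ in range(3)]
        raw = (parts[0][:, None, None] + parts[1][None, :, None]
               + parts[2][None, None, :])
        g = FreeEnergyField.from_values(grid, raw)
        p = probability_from_free_energy(g)
        g2, _ = project(g, p, (1, 2))
        expect = parts[0][:, None] + parts[1][None, :]
        diff = (g2.values - g2.values[0, 0]) - (expect - expect[0, 0])
        assert np.abs(diff).max() < 1e-10

    @pytest.mark.parametrize("pair,drop", [((1, 2), 2), ((2, 3), 0),
                                           ((1, 3), 1)])
    def test_matches_double_loop_oracle(self, random_energy_field,
                                        random_probability_field, pair, drop):
        g, p = random_energy_field, random_probability_field
        g2, p2 = project(g, p, pair)
        expect, m2 = project_loop(g, p, drop)
        assert np.array_equal(g2.mask, m2)
        shifted = expect - expect[m2].min()
        assert np.abs(g2.values[m2] - shifted[m2]).max() < 1e-12
        # projected P is Boltzmann-normalized from projected G, not summed
        z = np.exp(-g2.values[m2]).sum()
        assert np.abs(p2.values[m2] - np.exp(-g2.values[m2]) / z).max() < 1e-12


# ----------------------------------------------------------- convergence

class TestConvergence:
    def test_identical_checkpoints_give_zero(self, grid, rng):
        p = make_probability(grid, rng)
        series = CheckpointSeries(taus=[1.0, 2.0, 3.0], fields=[p, p, p])
        assert [l for _, l in convergence_series(series)] == [0.0, 0.0]

    def test_disjoint_one_hot_distributions_give_two(self, grid):
        w1 = np.zeros(grid.shape)
        w1[0, 0, 0] = 1.0
        w2 = np.zeros(grid.shape)
        w2[5, 5, 5] = 1.0
        p1 = ProbabilityField.from_weights(grid, w1)
        p2 = ProbabilityField.from_weights(grid, w2)
        series = CheckpointSeries(taus=[1.0, 2.0], fields=[p1, p2])
        (_, l), = convergence_series(series)
        assert l == pytest.approx(2.0, abs=1e-15)

    def test_random_pair_matches_direct_sum(self, grid, rng):
        p1 = make_probability(grid, rng, sparsity=0.4)
        p2 = make_probability(grid, rng, sparsity=0.4)
        series = CheckpointSeries(taus=[0.0, 1.0], fields=[p1, p2])
        (_, l), = convergence_series(series)
        direct = 0.0
        for idx in np.ndindex(grid.shape):
            a = p1.values[idx] if p1.mask[idx] else 0.0
            b = p2.values[idx] if p2.mask[idx] else 0.0
            direct += (b - a) ** 2
        assert l == pytest.approx(direct, abs=1e-14)

    def test_single_checkpoint_errors(self, grid, rng):
        series = CheckpointSeries(taus=[1.0],
                                  fields=[make_probability(grid, rng)])
        with pytest.raises(ValueError):
            convergence_series(series)

    def test_tau_must_increase(self, grid, rng):
        p = make_probability(grid, rng)
        with pytest.raises(ValueError):
            CheckpointSeries(taus=[2.0, 1.0], fields=[p, p])


# ------------------------------------------------------------ Welch test

def welch_formula(a, b):
    """Textbook Welch t and Welch-Satterthwaite dof, hand-coded."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, dof


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_coded_formula(self):
        from scipy import stats

        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        t, p = welch_t_test(a, b)
        t_ref, dof = welch_formula(a, b)
        p_ref = 2 * stats.t.sf(abs(t_ref), dof)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(0, 1, 5).tolist()
        b = rng.normal(1, 2, 7).tolist()
        t1, p1 = welch_t_test(a, b)
        t2, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_small_or_degenerate_samples_error(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])
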