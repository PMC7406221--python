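"""Exponential fitting, best-prefix selection and transcript classes."""

import numpy as np
import pandas as pd
import pytest

from rnadecay import fit_exponential, select_best_prefix
from rnadecay.decay import LN2, DecayModel, classify_transcript
from rnadecay.errors import ContractError, NoSignalError
from rnadecay.io import DEFAULT_TIME_GRID

GRID = np.array(DEFAULT_TIME_GRID)


def _series(t_half=1.0, a0=100.0, reps=3):
    t = np.tile(GRID, reps)
    return t, a0 * 2.0 ** (-t / t_half)


def test_exact_exponential_recovers_halflife_and_r2():
    t, a = _series(t_half=1.0)
    fit = fit_exponential(t, a)
    assert np.isclose(fit.t_half, 1.0, rtol=1e-12)
    assert np.isclose(fit.r2, 1.0)
    assert np.isclose(fit.t_half * fit.k, LN2)


def test_constant_abundance_flags_infinite_halflife():
    t = np.tile(GRID, 3)
    fit = fit_exponential(t, np.full_like(t, 50.0))
    assert fit.t_half == np.inf


def test_all_zero_signals_no_signal():
    t = np.tile(GRID, 3)
    with pytest.raises(NoSignalError):
        fit_exponential(t, np.zeros_like(t))


def test_needs_three_distinct_times():
    with pytest.raises(ContractError):
        fit_exponential([0, 0, 1, 1], [4, 4, 2, 2])


def test_halflife_invariant_to_abundance_scaling():
    t, a = _series(t_half=0.8)
    rng = np.random.default_rng(3)
    noisy = a * np.exp(rng.normal(0, 0.1, a.size))
    f1 = fit_exponential(t, noisy)
    f2 = fit_exponential(t, noisy * 1e4)
    assert np.isclose(f1.t_half, f2.t_half, rtol=1e-12)
    assert np.isclose(f1.r2, f2.r2, rtol=1e-12)


def test_decay_rate_equivariant_to_time_units():
    t, a = _series(t_half=2.0)
    rng = np.random.default_rng(4)
    noisy = a * np.exp(rng.normal(0, 0.05, a.size))
    per_min = fit_exponential(t, noisy)
    per_sec = fit_exponential(t * 60.0, noisy)
    assert np.isclose(per_sec.k, per_min.k / 60.0, rtol=1e-12)
    assert np.isclose(per_sec.t_half, per_min.t_half * 60.0, rtol=1e-12)


def test_log_fit_close_to_nonlinear_grid_search_oracle():
    """NB-noised curve, true t1/2 = 0.75 min: the log-space estimate agrees
    with a brute-force linear-space least-squares oracle within 15%."""
    rng = np.random.default_rng(11)
    t = np.tile(GRID, 3)
    mu = 500.0 * 2.0 ** (-t / 0.75)
    size = 10.0
    a = rng.negative_binomial(size, size / (size + mu)).astype(float)
    fit = fit_exponential(t, a)

    k_grid = np.linspace(0.2, 3.0, 1401)
    a0_grid = np.linspace(200, 900, 141)
    best = (np.inf, None)
    for k in k_grid:
        curve = np.exp(-k * t)
        for a0 in a0_grid:
            sse = np.sum((a - a0 * curve) ** 2)
            if sse < best[0]:
                best = (sse, LN2 / k)
    assert abs(fit.t_half - best[1]) / best[1] < 0.15


def test_best_prefix_ties_broken_toward_all_points():
    t, a = _series(t_half=1.0)
    prefix, fit = select_best_prefix(t, a, GRID)
    assert prefix == 7
    assert np.isclose(fit.r2, 1.0)


def test_best_prefix_found_by_direct_r2_comparison():
    """Exponential decay until 2.5 min, then a flat floor: the chosen
    prefix maximizes R^2 over all five candidate fits."""
    t = np.tile(GRID, 3)
    a = 100.0 * 2.0 ** (-t / 0.8)
    a[t > 2.5] = 3.0  # count floor at the last three time points
    prefix, fit = select_best_prefix(t, a, GRID)
    r2s = {}
    for p in (3, 4, 5, 6, 7):
        mask = np.isin(t, GRID[:p])
        r2s[p] = fit_exponential(t[mask], a[mask]).r2
    assert prefix == max(sorted(r2s), key=lambda p: (round(r2s[p], 12), p))
    assert prefix == 4
    assert np.isclose(fit.r2, r2s[4])


def test_prefix_three_uses_first_three_grid_times():
    t, a = _series()
    mask = np.isin(t, GRID[:3])
    fit = fit_exponential(t[mask], a[mask])
    assert fit.n_points == 9
    assert set(np.unique(t[mask])) == {0.0, 0.5, 1.0}


class TestClassification:
    def _fit(self):
        t, a = _series(t_half=1.0)
        return select_best_prefix(t, a, GRID)

    def test_final_ratio_above_half_is_stable(self):
        p, f = self._fit()
        row = classify_transcript(1e4, 100.0, 60.0, p, f)
        assert row["class"] == "stable" and np.isnan(row["t_half"])

    def test_low_total_reads_is_no_reads(self):
        p, f = self._fit()
        row = classify_transcript(10.0, 100.0, 0.0, p, f)
        assert row["class"] == "no_reads"

    def test_poor_fit_is_low_r2(self):
        t = np.tile(GRID, 3)
        a = 50.0 + 40.0 * np.tile([1, -1, 1, -1, 1, -1, 1], 3)  # sawtooth
        p, f = select_best_prefix(t, a, GRID)
        row = classify_transcript(1e4, a[0], 1.0, p, f, min_r2=0.5)
        assert f.r2 < 0.5
        assert row["class"] == "low_r2"

    def test_good_fit_is_decay_with_halflife(self):
        p, f = self._fit()
        row = classify_transcript(1e4, 100.0, 0.01, p, f)
        assert row["class"] == "decay"
        assert np.isclose(row["t_half"] * row["k"], LN2)


def test_class_fractions_sum_to_one(default_results):
    _, res = default_results
    assert np.isclose(res.class_fractions.sum(), 1.0)
    assert res.class_counts.sum() == len(res.table)


def test_stable_fraction_recovered():
    import rnadecay as rd
    from rnadecay.simulate import SimConfig, make_fixture
    cfg = SimConfig(n_genes=200, stable_fraction=0.1, depth=200.0,
                    dispersion=0.05, seed=21)
    fx = make_fixture("custom-stable", config=cfg)
    factors = rd.compute_normalization_factors(
        fx.counts, fx.manifest, rd.default_included_ids(fx.manifest))
    res = rd.DecayModel.from_counts(fx.counts, factors).fit()
    truth_frac = fx.truth["stable"].mean()
    est_frac = res.class_fractions["stable"]
    assert abs(est_frac - truth_frac) < 0.05


def test_summary_reports_median(noiseless_results):
    _, res = noiseless_results
    text = res.summary()
    assert "median" in text and "decay" in text


def test_model_requires_first_and_last_timepoints(tiny_fixture):
    import rnadecay as rd
    fx = tiny_fixture
    factors = rd.compute_normalization_factors(
        fx.counts, fx.manifest, rd.default_included_ids(fx.manifest))
    ab = rd.normalize(fx.counts, factors)
    keep = fx.counts.samples["time"] > 0
    with pytest.raises(ContractError):
        DecayModel(ab.loc[:, keep.values], fx.counts.gene_counts(),
                   fx.counts.samples[keep.values], grid=GRID)
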