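"""Spike-in calibration and normalization-factor contracts."""

import numpy as np
import pandas as pd
import pytest

from rnadecay import (CountMatrix, compute_normalization_factors,
                      default_included_ids, fit_spikein_curve, normalize,
                      qc_spikein_fits, study_spikein_manifest)
from rnadecay.errors import CalibrationError, ContractError


def _cm(spike_counts: dict, gene_counts=None, times=None):
    """One-or-more-sample CountMatrix with the standard spike-in manifest."""
    manifest = study_spikein_manifest()
    samples = list(next(iter(spike_counts.values())).keys()) \
        if isinstance(next(iter(spike_counts.values())), dict) else None
    if samples is None:
        spike_counts = {k: {"s1": v} for k, v in spike_counts.items()}
        samples = ["s1"]
    rows = {}
    for sid in manifest.index:
        rows[sid] = [spike_counts.get(sid, {}).get(s, 0.0) for s in samples]
    for gid, vals in (gene_counts or {}).items():
        rows[gid] = [vals[s] for s in samples]
    counts = pd.DataFrame(rows, index=samples).T
    meta = pd.DataFrame({
        "replicate": ["A"] * len(samples),
        "time": times or list(range(len(samples))),
    }, index=pd.Index(samples, name="sample_id"))
    meta["time"] = meta["time"].astype(float)
    return CountMatrix(counts=counts, samples=meta,
                       spikein_ids=list(manifest.index)), manifest


def test_proportional_counts_give_slope_one_r2_one():
    manifest = study_spikein_manifest()
    counts = {sid: 7.0 * manifest.loc[sid, "copies_per_cell"]
              * manifest.loc[sid, "length"] for sid in manifest.index}
    cm, manifest = _cm(counts)
    fit = fit_spikein_curve(cm, manifest, "s1")
    assert np.isclose(fit.slope, 1.0)
    assert np.isclose(fit.r2, 1.0)


def test_user_exclusion_of_saturated_spikein():
    manifest = study_spikein_manifest()
    counts = {sid: 5.0 * manifest.loc[sid, "copies_per_cell"]
              * manifest.loc[sid, "length"] for sid in manifest.index}
    cm, manifest = _cm(counts)
    high = manifest["copies_per_cell"].idxmax()
    fit = fit_spikein_curve(cm, manifest, "s1", exclude=[high])
    assert high not in fit.included_ids
    assert fit.excluded_ids[high] == "user-excluded"
    assert default_included_ids(manifest) == \
        [s for s in manifest.index if s != high]


def test_zero_count_spikein_excluded_with_reason():
    manifest = study_spikein_manifest()
    counts = {sid: 5.0 * manifest.loc[sid, "copies_per_cell"]
              for sid in manifest.index}
    counts["spike_geneH"] = 0.0
    cm, manifest = _cm(counts)
    fit = fit_spikein_curve(cm, manifest, "s1")
    assert fit.excluded_ids["spike_geneH"] == "zero count"


def test_too_few_usable_points_is_calibration_error():
    manifest = study_spikein_manifest()
    counts = {sid: 0.0 for sid in manifest.index}
    counts["spike_geneD"] = 10.0
    counts["spike_geneF"] = 100.0
    cm, manifest = _cm(counts)
    with pytest.raises(CalibrationError):
        fit_spikein_curve(cm, manifest, "s1")


def test_fit_matches_normal_equations_on_outlier_data():
    """4 points with one 2x outlier: OLS coefficients from an independent
    normal-equations solve."""
    manifest = study_spikein_manifest().iloc[:4].copy()
    manifest["copies_per_cell"] = [0.1, 1.0, 10.0, 100.0]
    base = {sid: 3.0 * manifest.loc[sid, "copies_per_cell"]
            * manifest.loc[sid, "length"] for sid in manifest.index}
    outlier = manifest.index[2]
    base[outlier] *= 2.0
    cm, _ = _cm(base)
    cm.spikein_ids = list(manifest.index)
    fit = fit_spikein_curve(cm, manifest, "s1")
    x = np.log10(manifest["copies_per_cell"].to_numpy())
    y = np.log10(np.array([base[s] for s in manifest.index])
                 / manifest["length"].to_numpy() * 1e3)
    A = np.vstack([x, np.ones_like(x)]).T
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert np.isclose(fit.slope, beta[0])
    assert np.isclose(fit.intercept, beta[1])


def test_qc_flags_low_r2_samples():
    from rnadecay.spikein import SpikeInFit
    fits = [SpikeInFit("a", 1, 0, 0.99, [], {}),
            SpikeInFit("b", 1, 0, 0.5, [], {})]
    rep = qc_spikein_fits(fits)
    assert bool(rep.loc["a", "pass"]) and not bool(rep.loc["b", "pass"])


def test_equal_sums_give_unit_factors():
    counts = {"spike_geneD": {"s1": 100.0, "s2": 100.0, "s3": 100.0},
              "spike_geneF": {"s1": 100.0, "s2": 100.0, "s3": 100.0},
              "spike_geneG": {"s1": 0.0, "s2": 0.0, "s3": 0.0}}
    cm, manifest = _cm(counts, times=[0, 5, 10])
    f = compute_normalization_factors(cm, manifest)
    assert np.allclose(f.factors, 1.0)


def test_factor_is_reference_over_sample_ratio():
    counts = {"spike_geneD": {"s1": 200.0, "s2": 100.0}}
    cm, manifest = _cm(counts, times=[0, 10])
    f = compute_normalization_factors(cm, manifest)
    assert np.allclose(f.factors[["s1", "s2"]], [1.0, 2.0])


def test_zero_spikein_sum_names_sample():
    counts = {"spike_geneD": {"s1": 200.0, "s2": 0.0}}
    cm, manifest = _cm(counts, times=[0, 10])
    with pytest.raises(CalibrationError, match="s2"):
        compute_normalization_factors(cm, manifest)


def test_normalize_multiplies_and_drops_spikeins():
    counts = {"spike_geneD": {"s1": 200.0, "s2": 100.0}}
    genes = {"g1": {"s1": 10.0, "s2": 10.0}}
    cm, manifest = _cm(counts, gene_counts=genes, times=[0, 10])
    f = compute_normalization_factors(cm, manifest)
    norm = normalize(cm, f)
    assert norm.loc["g1", "s2"] == 20.0
    assert set(norm.index) == {"g1"}
    # defining property: post-normalization spike-in sums identical
    sums = cm.spike_counts().sum(axis=0) * f.factors
    assert np.allclose(sums, sums.iloc[0])


def test_missing_factor_is_contract_error():
    counts = {"spike_geneD": {"s1": 200.0, "s2": 100.0}}
    cm, manifest = _cm(counts, times=[0, 10])
    f = compute_normalization_factors(cm, manifest)
    f.table = f.table.iloc[:1]
    with pytest.raises(ContractError):
        normalize(cm, f)


def test_normalization_absorbs_global_rescaling_of_one_sample():
    """Multiplying every count of one sample by c leaves the normalized
    abundances unchanged."""
    counts = {"spike_geneD": {"s1": 100.0, "s2": 80.0},
              "spike_geneF": {"s1": 50.0, "s2": 40.0}}
    genes = {"g1": {"s1": 30.0, "s2": 24.0}}
    cm, manifest = _cm(counts, gene_counts=genes, times=[0, 10])
    base = normalize(cm, compute_normalization_factors(cm, manifest))
    cm2, _ = _cm(counts, gene_counts=genes, times=[0, 10])
    cm2.counts["s2"] *= 3.7
    scaled = normalize(cm2, compute_normalization_factors(cm2, manifest))
    assert np.allclose(base, scaled)


def test_factors_recover_simulated_depth_ratios(default_fixture):
    fx = default_fixture
    f = compute_normalization_factors(
        fx.counts, fx.manifest, default_included_ids(fx.manifest))
    ref = f.reference
    expected = fx.depths[ref] / fx.depths
    ratio = f.factors / expected
    assert np.abs(ratio - 1).max() < 0.05
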