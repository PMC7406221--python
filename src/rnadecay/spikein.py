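"""Spike-in calibration and absolute normalization of the time course.

Synthetic RNA spike-ins are added per cell before extraction, so the sum of
spike-in reads in a sample measures sequencing depth independently of the
shrinking mRNA pool.  Calibration checks that log10 length-normalized counts
respond linearly to log10 copies/cell; normalization rescales every sample
so its spike-in sum matches a reference sample, making abundances comparable
across the whole time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, ContractError
from .io import CountMatrix


@dataclass
class SpikeInFit:
    """Log-log least-squares calibration for one sample.

    slope/intercept are for log10(count per kilobase) ~ log10(copies/cell).
    """
    sample_id: str
    slope: float
    intercept: float
    r2: float
    included_ids: list = field(default_factory=list)
    excluded_ids: dict = field(default_factory=dict)  # id -> reason


def default_included_ids(manifest: pd.DataFrame, exclude_above: float = 999.0):
    """Drop spike-ins added above ``exclude_above`` copies/cell.

    The highest spike-in of the standard mix (1,000 copies/cell) saturates
    in practice and is not
    used for calibration; everything below is kept by default.
    """
    return list(manifest.index[manifest["copies_per_cell"] <= exclude_above])


def fit_spikein_curve(cm: CountMatrix, manifest: pd.DataFrame, sample_id: str,
                      exclude=()) -> SpikeInFit:
    """OLS of log10 counts-per-kb on log10 copies/cell for one sample."""
    counts = cm.spike_counts()[sample_id]
    excluded: dict = {sid: "user-excluded" for sid in exclude}
    usable = []
    for sid in manifest.index:
        if sid in excluded:
            continue
        if sid not in counts.index or counts[sid] <= 0:
            excluded[sid] = "zero count"
            continue
        usable.append(sid)
    if len(usable) < 3:
        raise CalibrationError(
            f"{sample_id}: only {len(usable)} usable spike-ins (need >= 3)")
    x = np.log10(manifest.loc[usable, "copies_per_cell"].to_numpy(float))
    cpk = counts[usable].to_numpy(float) / manifest.loc[usable, "length"].to_numpy(float) * 1e3
    y = np.log10(cpk)
    res = stats.linregress(x, y)
    return SpikeInFit(sample_id=sample_id, slope=float(res.slope),
                      intercept=float(res.intercept), r2=float(res.rvalue ** 2),
                      included_ids=usable, excluded_ids=excluded)


def qc_spikein_fits(fits, min_r2: float = 0.97) -> pd.DataFrame:
    """Flag samples whose calibration r2 falls below ``min_r2``.

    The default sits just below the calibration quality of a healthy run
    (r2 around 0.97 and up), which therefore passes untouched.
    """
    rep = pd.DataFrame(
        {"slope": [f.slope for f in fits],
         "intercept": [f.intercept for f in fits],
         "r2": [f.r2 for f in fits]},
        index=pd.Index([f.sample_id for f in fits], name="sample_id"))
    rep["pass"] = rep["r2"] >= min_r2
    return rep


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative factors that equalize spike-in sums."""
    table: pd.DataFrame           # index sample_id; columns factor, spikein_sum
    reference: str

    @property
    def factors(self) -> pd.Series:
        return self.table["factor"]


def compute_normalization_factors(cm: CountMatrix, manifest: pd.DataFrame,
                                  included_ids=None,
                                  reference: str = "global-t0") -> NormalizationFactors:
    """factor(sample) = spikein_sum(reference) / spikein_sum(sample).

    ``reference`` selects the anchor whose spike-in sum all samples are
    scaled to: ``"global-t0"`` (default) uses the t=0 sample of the first
    replicate so sums are identical across the entire time course;
    ``"per-replicate-t0"`` anchors each replicate to its own t=0 sample;
    any sample id is also accepted.
    """
    if included_ids is None:
        included_ids = list(manifest.index)
    spikes = cm.spike_counts().reindex(pd.Index(included_ids)).fillna(0.0)
    sums = spikes.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise CalibrationError(
            f"zero spike-in sum in sample(s) {list(zero.index)}")

    samples = cm.samples
    if reference == "per-replicate-t0":
        ref_of = {}
        for rep, grp in samples.groupby("replicate"):
            t0 = grp.index[grp["time"] == grp["time"].min()]
            for sid in grp.index:
                ref_of[sid] = t0[0]
        factor = pd.Series({sid: sums[ref_of[sid]] / sums[sid]
                            for sid in samples.index})
        ref_label = "per-replicate-t0"
    else:
        if reference == "global-t0":
            t0 = samples[samples["time"] == samples["time"].min()]
            ref = t0.index[0]
        else:
            if reference not in samples.index:
                raise ContractError(f"reference sample {reference!r} unknown")
            ref = reference
        factor = sums[ref] / sums
        ref_label = ref
    tab = pd.DataFrame({"factor": factor, "spikein_sum": sums})
    tab.index.name = "sample_id"
    return NormalizationFactors(table=tab, reference=ref_label)


def normalize(cm: CountMatrix, factors: NormalizationFactors) -> pd.DataFrame:
    """Multiply each sample's gene counts by its factor; drop spike-in rows."""
    missing = set(cm.counts.columns) - set(factors.table.index)
    if missing:
        raise ContractError(f"samples without a factor: {sorted(missing)}")
    f = factors.factors.reindex(cm.counts.columns)
    return cm.gene_counts().mul(f, axis=1)
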