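"""Reading and writing of the tabular formats the pipeline touches.

Count files are per-sample two-column TSV in the HTSeq-count dialect
(feature id, integer count; special ``__*`` summary rows are dropped and
logged).  A sample sheet maps each count file to a replicate label and the
time in minutes after rifampin addition.  Half-life tables and spike-in
manifests are plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ParameterError

log = logging.getLogger(__name__)

#: The protocol's sampling grid, in minutes after rifampin addition.
DEFAULT_TIME_GRID = (0.0, 0.5, 1.0, 2.5, 5.0, 7.5, 10.0)


@dataclass
class CountMatrix:
    """Raw read counts for genes and spike-ins across a time course.

    Attributes
    ----------
    counts : DataFrame, features x samples
        Non-negative counts.  Floats are allowed so that noiseless
        (expected-value) simulations can round-trip exactly.
    samples : DataFrame indexed by sample id
        Columns ``replicate`` (label) and ``time`` (minutes, >= 0).
    spikein_ids : list of str
        Feature ids that are spike-ins; disjoint from gene ids.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    spikein_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (np.asarray(self.counts.values) < 0).any():
            raise FormatError("negative counts in count matrix")
        if not set(self.counts.columns) == set(self.samples.index):
            raise ContractError("count columns and sample sheet disagree")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index.difference(pd.Index(self.spikein_ids), sort=False)

    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.gene_ids]

    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[pd.Index(self.spikein_ids)]

    @property
    def time_grid(self) -> np.ndarray:
        return np.array(sorted(self.samples["time"].unique()))


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample_id, path, replicate, time."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str})
    required = {"sample_id", "replicate", "time"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet is missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    if (sheet["time"] < 0).any():
        raise FormatError("negative time in sample sheet")
    return sheet.set_index("sample_id")


def _read_one_count_file(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t", header=None, names=["feature", "count"],
                      dtype={"feature": str})
    special = tab["feature"].str.startswith("__")
    if special.any():
        log.info("%s: dropped %d HTSeq summary rows", path, int(special.sum()))
        tab = tab[~special]
    counts = pd.to_numeric(tab["count"], errors="coerce")
    if counts.isna().any():
        raise FormatError(f"{path}: non-numeric count")
    if (counts < 0).any():
        raise FormatError(f"{path}: negative count")
    if not np.allclose(counts, np.round(counts)):
        raise FormatError(f"{path}: non-integer count")
    if tab["feature"].duplicated().any():
        dup = tab["feature"][tab["feature"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    return pd.Series(counts.values, index=tab["feature"].values)


def read_counts(sheet: pd.DataFrame, base_dir=None, spikein_ids=(),
                time_grid=DEFAULT_TIME_GRID) -> CountMatrix:
    """Join per-sample HTSeq-style count files into one :class:`CountMatrix`.

    Features absent from a sample are filled with 0 (logged).  Sample times
    must come from ``time_grid``.
    """
    if "path" not in sheet.columns:
        raise FormatError("sample sheet has no 'path' column")
    grid = np.asarray(time_grid, dtype=float)
    bad = ~np.isin(sheet["time"].astype(float), grid)
    if bad.any():
        raise FormatError(
            f"sample times {sorted(sheet['time'][bad].unique())} not on the "
            f"configured grid {list(grid)}")
    columns = {}
    for sample_id, row in sheet.iterrows():
        p = Path(row["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        columns[sample_id] = _read_one_count_file(p)
    counts = pd.DataFrame(columns)
    n_filled = int(counts.isna().sum().sum())
    if n_filled:
        log.info("filled %d missing (sample, feature) cells with 0", n_filled)
    counts = counts.fillna(0.0)
    spikes = [s for s in spikein_ids if s in counts.index]
    return CountMatrix(counts=counts,
                       samples=sheet[["replicate", "time"]].copy(),
                       spikein_ids=spikes)


def write_counts(cm: CountMatrix, out_dir) -> pd.DataFrame:
    """Write one two-column TSV per sample plus ``samples.tsv``; return the sheet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample_id in cm.counts.columns:
        p = out / f"counts_{sample_id}.tsv"
        cm.counts[sample_id].to_csv(p, sep="\t", header=False)
        paths.append(p.name)
    sheet = cm.samples.copy()
    sheet["path"] = paths
    sheet.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
    return sheet


# ---------------------------------------------------------------------------
# Spike-in manifest
# ---------------------------------------------------------------------------

def study_spikein_manifest() -> pd.DataFrame:
    """The six phiX174-derived spike-ins of the assay design.

    Copy numbers span 0.1-1,000 copies/cell; lengths are the approximate
    transcript lengths of the source genes/fragments.
    """
    man = pd.DataFrame(
        {"length": [990, 456, 1284, 528, 290, 190],
         "copies_per_cell": [0.1, 1.0, 10.0, 10.0, 100.0, 1000.0]},
        index=pd.Index(["spike_geneH", "spike_geneD", "spike_geneF",
                        "spike_geneG", "spike_frag290", "spike_frag190"],
                       name="spikein_id"))
    return man


def read_spikein_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col="spikein_id")
    if (man["length"] <= 0).any() or (man["copies_per_cell"] <= 0).any():
        raise FormatError("spike-in manifest requires positive length and copies_per_cell")
    return man


def write_spikein_manifest(man: pd.DataFrame, path) -> None:
    man.to_csv(path, sep="\t", index_label="spikein_id")


# ---------------------------------------------------------------------------
# Half-life table
# ---------------------------------------------------------------------------

HALFLIFE_COLUMNS = ["gene_id", "class", "half_life_min", "decay_rate_per_min",
                    "r2", "n_timepoints_used", "expression_level"]


def write_halflife_table(fits: pd.DataFrame, path) -> None:
    """Write the per-transcript classification/half-life table as TSV.

    ``half_life_min`` is empty unless class == "decay"; numeric columns are
    written in full precision so a read/write round trip is bit-identical.
    """
    out = fits.reset_index() if fits.index.name == "gene_id" else fits.copy()
    tab = pd.DataFrame({"gene_id": out["gene_id"], "class": out["class"]})
    decay = out["class"] == "decay"
    tab["half_life_min"] = out["t_half"].where(decay)
    tab["decay_rate_per_min"] = out["k"]
    tab["r2"] = out["r2"]
    tab["n_timepoints_used"] = out["n_timepoints_used"]
    tab["expression_level"] = out["expression_level"]
    tab.to_csv(path, sep="\t", index=False)


def read_halflife_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    tab = tab.rename(columns={"half_life_min": "t_half", "decay_rate_per_min": "k"})
    tab["t_half"] = tab["t_half"].where(tab["class"] == "decay")
    return tab.set_index("gene_id")


# ---------------------------------------------------------------------------
# MEME export
# ---------------------------------------------------------------------------

def export_meme_sets(fits: pd.DataFrame, utrs: pd.DataFrame, out_prefix,
                     n: int = 400, region: str = "3utr"):
    """Write FASTA sets for discriminative motif search.

    Primary set = the ``region`` sequences of the ``n`` longest-half-life
    decay-class genes; control set = the ``n`` shortest.  Coding strand only.
    Returns the two paths.
    """
    if region not in ("5utr", "3utr"):
        raise ParameterError(f"unknown region {region!r}")
    col = "utr5" if region == "5utr" else "utr3"
    decay = fits[fits["class"] == "decay"].copy()
    have_seq = utrs.index[utrs[col].str.len() > 0]
    decay = decay.loc[decay.index.intersection(have_seq)]
    if len(decay) < 2 * n:
        raise ParameterError(
            f"need at least 2 x n = {2 * n} decay-class genes (n = {n}) "
            f"with a {region} sequence, have {len(decay)}")
    ranked = decay.sort_values("t_half", ascending=False)
    stable_ids = ranked.index[:n]
    unstable_ids = ranked.index[-n:]
    paths = []
    for tag, ids in (("most_stable", stable_ids), ("least_stable", unstable_ids)):
        p = Path(f"{out_prefix}_{region}_{tag}.fasta")
        with open(p, "w") as fh:
            for gid in ids:
                fh.write(f">{gid}\n{utrs.loc[gid, col]}\n")
        paths.append(p)
    return tuple(paths)
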