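"""Synthetic rifampin run-off data with known ground truth.

The generator emulates a rifampin run-off experiment end to end: a random-composition
genome with annotated genes, planted intrinsic terminators (L- or
I-shaped) and UTR motifs with additive half-life effects, phiX174-style
spike-ins spanning 0.1-1,000 copies/cell, and a 7-time-point x 3-replicate
count table in which each transcript decays exponentially (optionally
after a run-off onset delay of tss_distance / elongation_rate), the mRNA
pool shrinks mechanistically through that decay, spike-ins track only
sequencing depth, and counts are negative-binomially overdispersed.

Every fixture records its ground truth so downstream stages can be tested
as parameter-recovery problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (DEFAULT_TIME_GRID, CountMatrix, study_spikein_manifest,
                 write_counts, write_spikein_manifest)

_UP_PAD = 160     # upstream spacer per gene; holds the 150-nt 5' UTR window
_DOWN_PAD = 280   # downstream spacer; holds the 270-nt terminator scan window


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Half-lives are log-normal with the given median (minutes) and log10
    standard deviation, right-truncated at ``halflife_max``; initial
    abundances are log-normal.  ``depth`` is the expected t=0 read count of
    a 1-kb gene at unit abundance; per-sample depths jitter log-normally.
    ``dispersion`` is the negative-binomial overdispersion (variance =
    mu + dispersion * mu^2; 0 switches sampling off and returns expected
    values).  ``elongation_rate`` (nt/s) converts a gene's distance from
    its operon's transcription start into a decay-onset delay; genes
    outside operons have zero delay.
    """
    n_genes: int = 500
    time_grid: tuple = DEFAULT_TIME_GRID
    n_replicates: int = 3
    halflife_median: float = 1.0
    halflife_log10_sd: float = 0.25
    halflife_max: float = 10.0
    expression_median: float = 1.0
    expression_log10_sd: float = 0.3
    dispersion: float = 0.1
    depth: float = 100.0
    depth_log10_sd: float = 0.05
    stable_fraction: float = 0.0
    elongation_rate: float = 25.0
    operon_size: int = 1
    share_operon_halflife: bool = True
    gene_length: tuple = (600, 1400)
    terminator_plan: dict | None = None          # {"L": frac, "I": frac, "none": frac}
    terminator_L_effect: float = 0.5             # minutes added to L genes
    motif_plan: list = field(default_factory=list)
    spikein_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.time_grid, float)
        if grid[0] != 0 or (np.diff(grid) <= 0).any():
            raise ParameterError("time grid must start at 0 and increase")
        for name in ("halflife_median", "expression_median", "depth"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.dispersion < 0 or not 0 <= self.stable_fraction <= 1:
            raise ParameterError("bad dispersion or stable_fraction")
        if self.terminator_plan is not None:
            tot = sum(self.terminator_plan.values())
            if abs(tot - 1) > 1e-9 or \
                    set(self.terminator_plan) - {"L", "I", "none"}:
                raise ParameterError("terminator_plan fractions must cover "
                                     "{L, I, none} and sum to 1")


_BASES = np.array(list("ACGT"))


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _hairpin_cassette(rng, ttype: str) -> str:
    """A strong planted hairpin (pure G/C stem) with or without a U-tract."""
    stem = rng.integers(8, 11)
    left = "".join(np.array(list("GC"))[rng.integers(0, 2, stem)])
    loop = _random_seq(rng, rng.integers(4, 7))
    tail = ("TTTTTTT" if ttype == "L"
            else "".join(np.array(list("ACG"))[rng.integers(0, 3, 10)]))
    return left + loop + _revcomp(left) + tail


def _build_flank(rng, ttype: str | None, config: SimConfig):
    """280-nt downstream flank with the planted terminator (if any)."""
    from .terminators import ScanParams, find_hairpins

    if ttype in ("L", "I"):
        offset = int(rng.integers(10, 21))
        cassette = _hairpin_cassette(rng, ttype)
        rest = _DOWN_PAD - offset - len(cassette)
        return _random_seq(rng, offset) + cassette + _random_seq(rng, rest)
    if ttype == "none":
        params = ScanParams()
        for _ in range(50):
            flank = _random_seq(rng, _DOWN_PAD)
            if not find_hairpins(flank, params):
                return flank
        raise ParameterError("could not sample a terminator-free flank")
    return _random_seq(rng, _DOWN_PAD)


_CATEGORIES = ("energy_metabolism", "translation", "transport",
               "regulation", "unknown")


def simulate_genome(config: SimConfig, rng=None):
    """Build genome, annotation and ground truth.

    Returns ``(genome dict, annotation DataFrame, truth DataFrame)``.  The
    layout guarantees >= 270 nt of intergenic room downstream of every stop
    codon, so terminator scanning never collides with a neighbor.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    m = max(1, config.operon_size)

    halflife = config.halflife_median * 10 ** (
        rng.normal(0.0, config.halflife_log10_sd, n))
    halflife = np.minimum(halflife, config.halflife_max)
    expression = config.expression_median * 10 ** (
        rng.normal(0.0, config.expression_log10_sd, n))
    stable = rng.random(n) < config.stable_fraction

    if config.terminator_plan is not None:
        types = rng.choice(list(config.terminator_plan),
                           p=list(config.terminator_plan.values()), size=n)
    else:
        types = np.array([""] * n, dtype=object)

    motif_planted = []  # per gene: list of (region, kmer, effect)
    for i in range(n):
        planted = []
        for spec_ in config.motif_plan:
            if rng.random() < spec_.get("fraction", 0.5):
                planted.append((spec_.get("region", "3utr"),
                                spec_["kmer"].upper(),
                                float(spec_.get("effect", 0.0))))
        motif_planted.append(planted)

    # operon blocks of consecutive genes share strand (and optionally t1/2)
    block_of = np.arange(n) // m
    strands = np.where(rng.random(n // m + 1) < 0.5, "+", "-")[block_of]
    if m > 1 and config.share_operon_halflife:
        for b in range(block_of.max() + 1):
            idx = np.flatnonzero(block_of == b)
            halflife[idx] = halflife[idx[0]]
            stable[idx] = stable[idx[0]]

    lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1,
                           size=n)
    contig_parts, ann_rows, truth_rows = [], [], []
    pos = 0
    for i in range(n):
        L = int(lengths[i])
        strand = strands[i]
        t_half = float(halflife[i])
        ttype = types[i] if types[i] else None
        for region, kmer, effect in motif_planted[i]:
            t_half += effect
        if types[i] == "L":
            t_half += config.terminator_L_effect
        t_half = min(t_half, config.halflife_max)

        upstream = _random_seq(rng, _UP_PAD)
        cds = "ATG" + _random_seq(rng, L - 6) + "TAA"
        flank = _build_flank(rng, ttype, config)
        # plant motifs inside the UTR windows on the coding strand
        for region, kmer, _ in motif_planted[i]:
            k = len(kmer)
            if region == "3utr":
                lo = 60 if ttype in ("L", "I") else 0
                p0 = int(rng.integers(lo, 100 - k + 1))
                flank = flank[:p0] + kmer + flank[p0 + k:]
            else:
                p0 = int(rng.integers(_UP_PAD - 150, _UP_PAD - k + 1))
                upstream = upstream[:p0] + kmer + upstream[p0 + k:]
        cassette = upstream + cds + flank
        if strand == "+":
            gstart = pos + _UP_PAD
        else:
            cassette = _revcomp(cassette)
            gstart = pos + _DOWN_PAD
        gend = gstart + L

        if m > 1:
            op_id = f"op{block_of[i]:04d}"
            block = np.flatnonzero(block_of == block_of[i])
            within = i - int(block[0])
            op_index = within + 1 if strand == "+" else len(block) - within
            tss_distance = sum(int(lengths[j]) + _UP_PAD + _DOWN_PAD
                               for j in np.flatnonzero(block_of == block_of[i])
                               if (j - i) * (1 if strand == "+" else -1) < 0)
        else:
            op_id, op_index, tss_distance = "", np.nan, 0

        gid = f"g{i:04d}"
        ann_rows.append({
            "gene_id": gid, "seq_id": "sim_1", "start": gstart, "end": gend,
            "strand": strand, "category": str(rng.choice(_CATEGORIES)),
            "operon_id": op_id, "operon_index": op_index})
        truth_rows.append({
            "gene_id": gid,
            "true_halflife": np.inf if stable[i] else t_half,
            "stable": bool(stable[i]),
            "true_expression": float(expression[i]),
            "terminator_type": types[i] if types[i] else "none",
            "planted_motifs": ";".join(f"{r}:{kmer}"
                                       for r, kmer, _ in motif_planted[i]),
            "operon_id": op_id, "operon_index": op_index,
            "tss_distance": int(tss_distance), "gene_length": L})
        contig_parts.append(cassette)
        pos += len(cassette)

    genome = {"sim_1": "".join(contig_parts)}
    ann_cols = ["gene_id", "seq_id", "start", "end", "strand", "category",
                "operon_id", "operon_index"]
    truth_cols = ["gene_id", "true_halflife", "stable", "true_expression",
                  "terminator_type", "planted_motifs", "operon_id",
                  "operon_index", "tss_distance", "gene_length"]
    annotation = pd.DataFrame(ann_rows, columns=ann_cols)
    truth = pd.DataFrame(truth_rows, columns=truth_cols).set_index("gene_id")
    return genome, annotation, truth


def _nb_draw(rng, mu, dispersion):
    mu = np.asarray(mu, float)
    if dispersion <= 0:
        return mu.copy()
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mu, 1e-300))
    return rng.negative_binomial(size, p).astype(float)


def simulate_timecourse(truth: pd.DataFrame, config: SimConfig, rng=None,
                        manifest: pd.DataFrame | None = None):
    """Draw the 7 x n_replicates count table plus spike-ins.

    Expected gene abundance: a_i(t) = A0_i * 2**(-max(0, t - d_i) / t1/2,i)
    with onset delay d_i = tss_distance_i / (elongation_rate * 60) minutes;
    stable genes stay at A0.  Gene counts are NB with mean
    depth_s * a_i(t) * length_i/1000; spike-in counts are Poisson with mean
    depth_s * copies_per_cell * length/1000 * spikein_scale, independent of
    the shrinking mRNA pool.  Returns (CountMatrix, per-sample depths).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if manifest is None:
        manifest = study_spikein_manifest()
    t_half = truth["true_halflife"].to_numpy(float)
    a0 = truth["true_expression"].to_numpy(float)
    lscale = truth["gene_length"].to_numpy(float) / 1e3
    if config.elongation_rate > 0:
        delay = truth["tss_distance"].to_numpy(float) / (config.elongation_rate * 60.0)
    else:
        delay = np.zeros(len(truth))

    rep_labels = [chr(ord("A") + r) for r in range(config.n_replicates)]
    columns, meta, depths = {}, [], {}
    for rep in rep_labels:
        for t in config.time_grid:
            sid = f"{rep}_t{t:g}"
            depth_s = config.depth * 10 ** rng.normal(0.0, config.depth_log10_sd)
            depths[sid] = depth_s
            dt = np.maximum(0.0, t - delay)
            decay = np.where(np.isfinite(t_half), 2.0 ** (-dt / t_half), 1.0)
            gene_mu = depth_s * a0 * lscale * decay
            spike_mu = (depth_s * config.spikein_scale
                        * manifest["copies_per_cell"].to_numpy(float)
                        * manifest["length"].to_numpy(float) / 1e3)
            # genes carry biological NB overdispersion; spike-ins are added
            # in vitro and only see technical (Poisson) counting noise
            spike_counts = (rng.poisson(spike_mu).astype(float)
                            if config.dispersion > 0 else spike_mu)
            columns[sid] = np.concatenate([
                _nb_draw(rng, gene_mu, config.dispersion), spike_counts])
            meta.append({"sample_id": sid, "replicate": rep, "time": float(t)})
    index = pd.Index(list(truth.index) + list(manifest.index), name="feature")
    counts = pd.DataFrame(columns, index=index)
    samples = pd.DataFrame(meta).set_index("sample_id")
    cm = CountMatrix(counts=counts, samples=samples,
                     spikein_ids=list(manifest.index))
    return cm, pd.Series(depths, name="depth")


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    name: str
    config: SimConfig
    genome: dict
    annotation: pd.DataFrame
    truth: pd.DataFrame
    counts: CountMatrix
    depths: pd.Series
    manifest: pd.DataFrame

    def write(self, out_dir) -> dict:
        from .annotation import write_annotation, write_fasta
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fasta")
        write_annotation(self.annotation, out / "genes.gff3")
        write_counts(self.counts, out / "counts")
        write_spikein_manifest(self.manifest, out / "spikeins.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t")
        self.depths.to_csv(out / "depths.tsv", sep="\t",
                           index_label="sample_id")
        return {"genome": out / "genome.fasta", "gff": out / "genes.gff3",
                "counts": out / "counts", "manifest": out / "spikeins.tsv",
                "truth": out / "truth.tsv"}


FIXTURE_CONFIGS = {
    # 20 genes, 21 samples; end-to-end smoke fixture
    "tiny": SimConfig(n_genes=20, depth=200.0, dispersion=0.05, seed=101),
    # noise-free expected counts; exact-recovery fixture
    "noiseless": SimConfig(n_genes=100, depth=1000.0, dispersion=0.0,
                           depth_log10_sd=0.0, seed=7),
    # the reference noisy-recovery conditions
    "default": SimConfig(n_genes=500, depth=100.0, dispersion=0.1, seed=42),
    # operons of 4 sharing a half-life; onset delay visible along the operon
    "operon": SimConfig(n_genes=120, operon_size=4, depth=200.0,
                        dispersion=0.1, halflife_median=1.2,
                        halflife_log10_sd=0.0, seed=11),
    # planted L/I/none terminators with an L stability bonus
    "terminator": SimConfig(n_genes=300, depth=200.0, dispersion=0.1,
                            terminator_plan={"L": 0.35, "I": 0.35,
                                             "none": 0.30},
                            terminator_L_effect=0.5, seed=13),
    # one stabilizing 3' UTR 6-mer planted in half of 2,000 genes
    "ml": SimConfig(n_genes=2000, depth=300.0, dispersion=0.1,
                    halflife_log10_sd=0.15,
                    motif_plan=[{"region": "3utr", "kmer": "AGTTCG",
                                 "effect": 1.0, "fraction": 0.5}],
                    seed=17),
}

ML_PLANTED_MOTIF = ("3utr", "AGTTCG")


def make_fixture(name: str, out_dir=None, config: SimConfig | None = None) -> Fixture:
    """Deterministic named dataset bundle; optionally written to disk."""
    if config is None:
        if name not in FIXTURE_CONFIGS:
            raise ParameterError(
                f"unknown fixture {name!r}; known: {sorted(FIXTURE_CONFIGS)}")
        config = FIXTURE_CONFIGS[name]
    rng = np.random.default_rng(config.seed)
    genome, annotation, truth = simulate_genome(config, rng)
    manifest = study_spikein_manifest()
    cm, depths = simulate_timecourse(truth, config, rng, manifest)
    fx = Fixture(name=name, config=config, genome=genome,
                 annotation=annotation, truth=truth, counts=cm,
                 depths=depths, manifest=manifest)
    if out_dir is not None:
        fx.write(out_dir)
    return fx


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` re-keyed to ``seed`` (for seeded replications)."""
    return replace(config, seed=seed)
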