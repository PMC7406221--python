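"""Intrinsic (Rho-independent) terminator detection in 3' flanks.

A candidate terminator is an RNA hairpin — stem of 4-12 bp with at most 3
internal mismatches, loop of 3-8 nt — whose folding free energy is at or
below a species-specific cutoff (-11.618 kcal/mol by default) and whose
stem starts within 270 nt of the stop codon.  Hairpins followed by a
U-rich tract are L-shaped; hairpins without one are I-shaped.

Energetics use a transparent, versioned nearest-neighbor model shipped as
package data: Turner-style stacking free energies summed over consecutive
base pairs (G.U wobble counts as a weak pair, not a mismatch), a tabulated
hairpin-loop initiation penalty, and a flat +1.0 kcal/mol per mismatch.
This is scanner-grade ("WebGeSTer-like"), not a full secondary-structure
prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import StructuralError

# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

_DATA = json.loads(resources.files("rnadecay.data")
                   .joinpath("stack_energies.json").read_text())
STACK_TABLE = _DATA["stack"]
LOOP_PENALTY = {int(k): v for k, v in _DATA["hairpin_loop"].items()}
MISMATCH_PENALTY = float(_DATA["mismatch_penalty"])
ENERGY_MODEL_VERSION = _DATA["version"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_RNA = "ACGU"

# allowed pairs: Watson-Crick plus G.U wobble
_PAIR = np.zeros((5, 5), dtype=bool)
for a, b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIR[a, b] = True

# stack energy lookup over (a1, b1, a2, b2) codes; 0 where either pair invalid
_STACK = np.zeros((5, 5, 5, 5), dtype=np.float64)
for key, val in STACK_TABLE.items():
    p1, p2 = key.split(",")
    a1, b1 = _CODE[p1[0]], _CODE[p1[1]]
    a2, b2 = _CODE[p2[0]], _CODE[p2[1]]
    _STACK[a1, b1, a2, b2] = val


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode().translate(
        bytes.maketrans(b"ACGTUN", bytes([0, 1, 2, 3, 3, 4]))), dtype=np.uint8)


def loop_penalty(loop_len: int) -> float:
    if loop_len < 3:
        raise StructuralError("hairpin loop must be >= 3 nt")
    return LOOP_PENALTY[min(loop_len, max(LOOP_PENALTY))]


def fold_energy(left_arm_seq: str, right_arm_seq: str, loop_len: int,
                mismatch_positions=()) -> float:
    """Free energy (kcal/mol) of a hairpin given its arms and mismatches.

    Position ``j`` of the left arm (5'->3') pairs with position ``s-1-j`` of
    the right arm.  Stacks are summed over consecutive paired positions;
    each mismatch adds a flat penalty; the loop adds its initiation penalty.
    """
    s = len(left_arm_seq)
    if len(right_arm_seq) != s:
        raise StructuralError("arm lengths differ")
    mm = set(mismatch_positions)
    left = _encode(left_arm_seq)
    right = _encode(right_arm_seq)
    partner = right[::-1]  # partner[j] pairs with left[j]
    energy = loop_penalty(loop_len) + MISMATCH_PENALTY * len(mm)
    for j in range(s - 1):
        if j in mm or (j + 1) in mm:
            continue
        energy += _STACK[left[j], partner[j], left[j + 1], partner[j + 1]]
    return float(energy)


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    """Structural bounds of the terminator scan (study defaults)."""
    stem_min: int = 4
    stem_max: int = 12
    loop_min: int = 3
    loop_max: int = 8
    max_mismatch: int = 3
    max_distance_from_orf: int = 270
    dg_cutoff: float = -11.618

    def __post_init__(self):
        if self.stem_min > self.stem_max or self.loop_min > self.loop_max:
            raise StructuralError("inverted stem/loop bounds")
        if self.max_mismatch < 0 or self.dg_cutoff >= 0:
            raise StructuralError("max_mismatch >= 0 and dg_cutoff < 0 required")


@dataclass(frozen=True)
class Hairpin:
    """A candidate terminator hairpin, coordinates relative to the flank."""
    left_start: int
    stem: int
    loop: int
    mismatches: int
    delta_g: float

    @property
    def left_arm(self):
        return (self.left_start, self.left_start + self.stem)

    @property
    def loop_interval(self):
        a = self.left_start + self.stem
        return (a, a + self.loop)

    @property
    def right_arm(self):
        a = self.left_start + self.stem + self.loop
        return (a, a + self.stem)

    @property
    def end(self) -> int:
        return self.left_start + 2 * self.stem + self.loop


def find_hairpins(seq: str, params: ScanParams = ScanParams()):
    """All hairpins within the parameter bounds with energy <= cutoff.

    The terminal stem positions must pair (mismatches are internal), the
    hairpin must start within ``max_distance_from_orf`` of the flank start,
    and G.U wobble counts as a pair.  Returns hairpins sorted by
    (delta_g, left_start).
    """
    code = _encode(seq)
    n = len(code)
    found = []
    for s in range(params.stem_min, params.stem_max + 1):
        for l in range(params.loop_min, params.loop_max + 1):
            span = 2 * s + l
            m = min(n - span + 1, params.max_distance_from_orf + 1)
            if m <= 0:
                continue
            # left arm base j at i+j; its partner at i + s + l + (s-1-j)
            pairok = np.empty((s, m), dtype=bool)
            lcodes = []
            pcodes = []
            for j in range(s):
                cj = code[j:j + m]
                pj = code[span - 1 - j:span - 1 - j + m]
                pairok[j] = _PAIR[cj, pj]
                lcodes.append(cj)
                pcodes.append(pj)
            mism = s - pairok.sum(axis=0)
            valid = pairok[0] & pairok[s - 1] & (mism <= params.max_mismatch)
            if not valid.any():
                continue
            energy = np.full(m, loop_penalty(l))
            energy += MISMATCH_PENALTY * mism
            for j in range(s - 1):
                both = pairok[j] & pairok[j + 1]
                e = _STACK[lcodes[j], pcodes[j], lcodes[j + 1], pcodes[j + 1]]
                energy += np.where(both, e, 0.0)
            ok = valid & (energy <= params.dg_cutoff)
            for i in np.flatnonzero(ok):
                found.append(Hairpin(left_start=int(i), stem=s, loop=l,
                                     mismatches=int(mism[i]),
                                     delta_g=float(energy[i])))
    found.sort(key=lambda h: (h.delta_g, h.left_start, h.stem, h.loop))
    return found


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class TerminatorCall:
    gene_id: str
    type: str                 # "L", "I" or "none"
    hairpin: Hairpin | None
    u_tract_length: int


def classify_terminator(hairpins, downstream_source_seq: str, gene_id: str = "",
                        u_window: int = 8, min_u: int = 4,
                        max_gap: int = 2) -> TerminatorCall:
    """Call L / I / none from the best hairpin and its downstream U content.

    The minimum-free-energy hairpin wins (ties toward the stop codon).  The
    call is L when at least ``min_u`` U's fall in the ``u_window`` nt after
    the right arm and the first U starts within ``max_gap`` nt of the stem.
    """
    if not hairpins:
        return TerminatorCall(gene_id=gene_id, type="none", hairpin=None,
                              u_tract_length=0)
    best = min(hairpins, key=lambda h: (h.delta_g, h.left_start))
    window = downstream_source_seq[best.end:best.end + u_window].upper()
    is_u = [c in "TU" for c in window]
    u_count = sum(is_u)
    first_u = is_u.index(True) if any(is_u) else None
    ttype = "L" if (u_count >= min_u and first_u is not None
                    and first_u <= max_gap) else "I"
    return TerminatorCall(gene_id=gene_id, type=ttype, hairpin=best,
                          u_tract_length=u_count)


def scan_genes(ann: pd.DataFrame, genome: dict,
               params: ScanParams = ScanParams(),
               truncate_at_next: bool = True, **u_rule) -> pd.DataFrame:
    """One terminator call per gene from its coding-strand 3' flank."""
    from .annotation import threeprime_flank
    flanks = threeprime_flank(ann, genome, length=params.max_distance_from_orf,
                              truncate_at_next=truncate_at_next)
    rows = []
    for _, r in ann.iterrows():
        flank = flanks[r.gene_id]
        call = classify_terminator(find_hairpins(flank, params), flank,
                                   gene_id=r.gene_id, **u_rule)
        h = call.hairpin
        rows.append({
            "gene_id": r.gene_id, "type": call.type,
            "u_tract_length": call.u_tract_length,
            "delta_g": h.delta_g if h else np.nan,
            "flank_start": h.left_start if h else -1,
            "flank_end": h.end if h else -1,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def calls_to_bed(calls: pd.DataFrame, ann: pd.DataFrame, path) -> None:
    """BED6 of called hairpins; score = -deltaG x 10, rounded; strand-aware."""
    ann_ix = ann.set_index("gene_id")
    with open(path, "w") as fh:
        for gid, c in calls.iterrows():
            if c["type"] == "none":
                continue
            g = ann_ix.loc[gid]
            if g.strand == "+":
                start = int(g.end + c["flank_start"])
                end = int(g.end + c["flank_end"])
            else:
                start = int(g.start - c["flank_end"])
                end = int(g.start - c["flank_start"])
            score = int(round(-c["delta_g"] * 10))
            fh.write(f"{g.seq_id}\t{start}\t{end}\t{gid}:{c['type']}\t"
                     f"{score}\t{g.strand}\n")


def terminator_association(calls: pd.DataFrame, fits: pd.DataFrame) -> dict:
    """Half-life comparison across terminator classes (decay genes only).

    Returns per-type n and median half-life plus Bonferroni-adjusted Welch
    t-test p values over the three pairwise comparisons; groups with < 2
    members are excluded.
    """
    from scipy import stats

    decay = fits[fits["class"] == "decay"]
    merged = decay.join(calls[["type"]], how="inner")
    groups = {t: g["t_half"].to_numpy(float)
              for t, g in merged.groupby("type") if len(g) >= 2}
    summary = {t: {"n": len(v), "median_halflife": float(np.median(v))}
               for t, v in groups.items()}
    names = sorted(groups)
    pairwise = {}
    n_pairs = 3  # L/I, L/none, I/none — the family the adjustment covers
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.var(groups[a]) == 0 and np.var(groups[b]) == 0:
                p = 1.0 if np.mean(groups[a]) == np.mean(groups[b]) else 0.0
            else:
                p = float(stats.ttest_ind(groups[a], groups[b],
                                          equal_var=False).pvalue)
            pairwise[f"{a}_vs_{b}"] = min(1.0, p * n_pairs)
    return {"groups": summary, "pairwise_p_bonferroni": pairwise}
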