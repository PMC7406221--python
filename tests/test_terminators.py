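"""Hairpin energetics, scanning vs brute force, and L/I/none calls."""

import numpy as np
import pytest

from rnadecay import ScanParams, classify_terminator, find_hairpins, \
    fold_energy, terminator_association
from rnadecay.errors import StructuralError
from rnadecay.terminators import LOOP_PENALTY, MISMATCH_PENALTY, STACK_TABLE

BASES = np.array(list("ACGT"))


def brute_force_hairpins(seq, params=ScanParams()):
    """Independent naive enumeration of every qualifying hairpin."""
    def code(c):
        return {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}.get(c.upper(), 4)

    def pair(a, b):
        return (code(a), code(b)) in {(0, 3), (3, 0), (1, 2), (2, 1),
                                      (2, 3), (3, 2)}

    out = []
    n = len(seq)
    for i in range(min(n, params.max_distance_from_orf + 1)):
        for s in range(params.stem_min, params.stem_max + 1):
            for l in range(params.loop_min, params.loop_max + 1):
                if i + 2 * s + l > n:
                    continue
                left = seq[i:i + s]
                right = seq[i + s + l:i + 2 * s + l]
                mism = [j for j in range(s) if not pair(left[j],
                                                        right[s - 1 - j])]
                if 0 in mism or (s - 1) in mism:
                    continue
                if len(mism) > params.max_mismatch:
                    continue
                e = fold_energy(left, right, l, mism)
                if e <= params.dg_cutoff:
                    out.append((i, s, l, len(mism), round(e, 9)))
    return sorted(out)


def _random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def _planted_seq(rng, n=80):
    """Random sequence with a strong G/C hairpin written in."""
    stem = "".join(np.array(list("GC"))[rng.integers(0, 2, 9)])
    rc = stem.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    loop = _random_seq(rng, 4)
    pos = int(rng.integers(0, n - len(stem) * 2 - 4))
    base = _random_seq(rng, n)
    cass = stem + loop + rc
    return base[:pos] + cass + base[pos + len(cass):]


def test_energy_is_hand_sum_of_stacks_plus_loop_penalty():
    """6 G-C pairs, loop 4: five GC,GC stacks plus the loop-4 penalty."""
    e = fold_energy("GGGGGG", "CCCCCC", 4)
    assert np.isclose(e, 5 * STACK_TABLE["GC,GC"] + LOOP_PENALTY[4])


def test_each_mismatch_adds_flat_penalty():
    clean = fold_energy("GGCGGG", "CCCGCC", 4)
    one = fold_energy("GGAGGG", "CCCGCC", 4, mismatch_positions=[2])
    # the mismatch also breaks the two stacks flanking position 2
    broken = STACK_TABLE["GC,CG"] + STACK_TABLE["CG,GC"]
    assert np.isclose(one - clean, MISMATCH_PENALTY - broken, atol=1e-9)


def test_loop_below_three_rejected():
    with pytest.raises(StructuralError):
        fold_energy("GGGG", "CCCC", 2)


def test_poly_a_flank_has_no_hairpins():
    assert find_hairpins("A" * 60) == []


def test_weak_au_stem_fails_energy_cutoff():
    seq = "AAAA" + "GAGA" + "TTTT"     # 4 A-U pairs around a 4-nt loop
    e = fold_energy("AAAA", "TTTT", 4)
    assert e > ScanParams().dg_cutoff
    assert find_hairpins(seq) == []


@pytest.mark.parametrize("planted", [False, True])
def test_scanner_equals_brute_force(planted):
    rng = np.random.default_rng(42 if planted else 7)
    for _ in range(60):
        n = int(rng.integers(30, 101))
        seq = _planted_seq(rng, max(n, 40)) if planted else _random_seq(rng, n)
        got = sorted((h.left_start, h.stem, h.loop, h.mismatches,
                      round(h.delta_g, 9)) for h in find_hairpins(seq))
        assert got == brute_force_hairpins(seq)


def test_reported_hairpins_respect_scan_bounds():
    rng = np.random.default_rng(5)
    params = ScanParams()
    for _ in range(30):
        seq = _planted_seq(rng, 120)
        for h in find_hairpins(seq, params):
            assert params.stem_min <= h.stem <= params.stem_max
            assert params.loop_min <= h.loop <= params.loop_max
            assert h.mismatches <= params.max_mismatch
            assert h.delta_g <= params.dg_cutoff
            assert h.left_start <= params.max_distance_from_orf


def test_strand_symmetric_calls(terminator_fixture):
    """A gene's call depends only on its coding-strand flank, so plus- and
    minus-strand genes with planted terminators classify identically."""
    import pandas as pd

    from rnadecay import scan_genes
    fx = terminator_fixture
    calls = scan_genes(fx.annotation, fx.genome)
    merged = calls.join(fx.truth[["terminator_type"]]).join(
        fx.annotation.set_index("gene_id")["strand"])
    for strand, grp in merged.groupby("strand"):
        acc = (grp["type"] == grp["terminator_type"]).mean()
        assert acc >= 0.99, strand


def test_classification_rules():
    stem, loop = "GGCGCCGC", "TTAT"
    rc = stem.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    for tail, expected in (("TTTTTTTT", "L"), ("GCGAGCGA", "I")):
        seq = "AACA" + stem + loop + rc + tail + "ACGATCAG"
        hp = find_hairpins(seq)
        call = classify_terminator(hp, seq, gene_id="g")
        assert call.type == expected
        if expected == "L":
            assert call.u_tract_length >= 6
    none = classify_terminator([], "ACGT" * 10)
    assert none.type == "none" and none.hairpin is None


def test_association_identical_groups_capped_at_one():
    import pandas as pd
    fits = pd.DataFrame({
        "class": ["decay"] * 9,
        "t_half": [1.0, 2.0, 3.0] * 3,
    }, index=pd.Index([f"g{i}" for i in range(9)], name="gene_id"))
    calls = pd.DataFrame({
        "type": ["L"] * 3 + ["I"] * 3 + ["none"] * 3,
    }, index=fits.index)
    rep = terminator_association(calls, fits)
    assert all(p == 1.0 for p in rep["pairwise_p_bonferroni"].values())


def test_association_detects_planted_L_effect():
    """+0.5 min on 200 L genes vs 200 without: Bonferroni-adjusted p < 0.01."""
    import pandas as pd
    rng = np.random.default_rng(19)
    hl = np.r_[rng.normal(1.5, 0.5, 200), rng.normal(1.0, 0.5, 200)]
    fits = pd.DataFrame({
        "class": "decay", "t_half": hl,
    }, index=pd.Index([f"g{i}" for i in range(400)], name="gene_id"))
    calls = pd.DataFrame({"type": ["L"] * 200 + ["none"] * 200},
                         index=fits.index)
    rep = terminator_association(calls, fits)
    assert rep["pairwise_p_bonferroni"]["L_vs_none"] < 0.01
    assert rep["groups"]["L"]["median_halflife"] > \
        rep["groups"]["none"]["median_halflife"]


def test_bonferroni_triples_raw_p_and_caps():
    import pandas as pd
    from scipy import stats as ss
    rng = np.random.default_rng(3)
    a, b = rng.normal(1, 0.3, 50), rng.normal(1.2, 0.3, 50)
    fits = pd.DataFrame({"class": "decay", "t_half": np.r_[a, b]},
                        index=pd.Index([f"g{i}" for i in range(100)],
                                       name="gene_id"))
    calls = pd.DataFrame({"type": ["L"] * 50 + ["I"] * 50}, index=fits.index)
    rep = terminator_association(calls, fits)
    raw = ss.ttest_ind(a, b, equal_var=False).pvalue
    assert np.isclose(rep["pairwise_p_bonferroni"]["I_vs_L"],
                      min(1.0, raw * 3))
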