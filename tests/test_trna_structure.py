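"""Cloverleaf template folding and the per-arm mismatch census."""

import itertools

import numpy as np
import pytest

from mitochar import fold_cloverleaf, fold_feature, mismatch_census
from mitochar.errors import FeatureValidationError, NoCloverleafError
from mitochar.synthetic_data import make_trna
from mitochar.trna_structure import (
    AC_LOOP, ARMS, Layout, MIN_PAIRED, PAIR_SCORES, pair_class,
)


def brute_force_fold(seq, anticodon=None):
    """Independent oracle: flat enumeration of every template placement
    with direct scoring, same documented tie-break."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    anticodon = anticodon and anticodon.upper().replace("U", "T")
    best = None
    space = itertools.product(
        (0, 1), (6, 7), (1, 2, 3), (3, 4), range(4, 13), (0, 1, 2), (4, 5),
        (4, 5), range(5, 10), range(0, 5))
    for lead, acc, c1, d, dloop, c2, ac, t, tloop, tail in space:
        vloop = n - (lead + 2 * acc + c1 + 2 * d + dloop + c2 + 2 * ac
                     + AC_LOOP + 2 * t + tloop + tail)
        if not 3 <= vloop <= 23:
            continue
        layout = Layout(lead=lead, acc=acc, c1=c1, d=d, dloop=dloop, c2=c2,
                        ac=ac, vloop=vloop, t=t, tloop=tloop, tail=tail)
        a0 = layout.anticodon_start
        if anticodon is not None and seq[a0:a0 + 3] != anticodon:
            continue
        score = paired = 0
        for pairs in layout.stem_positions().values():
            for p5, p3 in pairs:
                cls = pair_class(seq[p5], seq[p3])
                score += PAIR_SCORES[cls]
                paired += cls != "mismatch"
        if paired < MIN_PAIRED:
            continue
        key = (-score, -paired, vloop, lead, acc, c1, d, dloop, c2, ac, t,
               tloop, tail)
        if best is None or key < best[0]:
            best = (key, layout, score)
    return best


def perfect_trna(length=71, anticodon="GAA", seed=3, gu=None):
    rng = np.random.default_rng(seed)
    return make_trna(length, anticodon, gu or {}, rng)


class TestFold:
    def test_perfect_stems_fold_with_zero_mismatches(self):
        seq, layout, _ = perfect_trna()
        fold = fold_cloverleaf(seq, anticodon="GAA")
        assert fold.layout == layout
        assert all(cls == "WC" for pairs in fold.arms.values()
                   for *_, cls in pairs)
        assert fold.anticodon_triplet == "GAA"

    def test_planted_gu_pairs_recovered_on_their_arm(self):
        seq, layout, _ = perfect_trna(gu={"dhu": 2}, length=72)
        fold = fold_cloverleaf(seq, anticodon="GAA")
        assert fold.arm_census("dhu") == {"GU": 2, "other": 0, "non_WC": 2}
        for arm in ("acceptor", "anticodon", "tpsic"):
            assert fold.arm_census(arm)["non_WC"] == 0

    def test_deterministic(self):
        seq, *_ = perfect_trna(seed=9)
        f1 = fold_cloverleaf(seq, anticodon="GAA")
        f2 = fold_cloverleaf(seq, anticodon="GAA")
        assert f1.layout == f2.layout and f1.arms == f2.arms

    def test_length_bounds_enforced(self):
        with pytest.raises(FeatureValidationError):
            fold_cloverleaf("ACGT" * 10)  # 40 nt, too short

    def test_unfoldable_sequence_raises(self):
        with pytest.raises(NoCloverleafError):
            fold_cloverleaf("A" * 70)  # A.A everywhere: no pairs at all

    def test_anticodon_constraint_centres_the_triplet(self):
        seq, layout, _ = perfect_trna(seed=5, length=70, anticodon="TTG")
        fold = fold_cloverleaf(seq, anticodon="TTG")
        a0 = fold.layout.anticodon_start
        assert fold.seq[a0:a0 + 3] == "TTG"
        loop_start = a0 - 2
        ac_pairs = fold.arms["anticodon"]
        # loop sits between the stem's 5' and 3' halves
        assert ac_pairs[-1][0] == loop_start  # 1-based: last 5' pair pos + 1 == loop start
        assert fold.layout == layout

    def test_dot_bracket_is_balanced(self):
        seq, *_ = perfect_trna(seed=6)
        db = fold_cloverleaf(seq, anticodon="GAA").dot_bracket()
        assert db.count("(") == db.count(")") == 21  # 7+4+5+5 max stems

    @pytest.mark.parametrize("seed,length,gu", [
        (0, 66, {}),
        (1, 70, {"acceptor": 1}),
        (2, 75, {"tpsic": 1, "dhu": 1}),
    ])
    def test_matches_brute_force_enumeration(self, seed, length, gu):
        """The fast search equals a flat enumeration of every placement
        (same score, same argmax under the documented tie-break)."""
        seq, _, _ = perfect_trna(seed=seed, length=length, gu=gu)
        fold = fold_cloverleaf(seq)
        key, layout, score = brute_force_fold(seq)
        assert fold.layout == layout
        assert fold.fold_score == score

    def test_matches_brute_force_with_anticodon_constraint(self):
        seq, _, _ = perfect_trna(seed=8, length=69)
        fold = fold_cloverleaf(seq, anticodon="GAA")
        _, layout, score = brute_force_fold(seq, anticodon="GAA")
        assert fold.layout == layout and fold.fold_score == score


class TestRecovery:
    def test_planted_structure_recovery_rate(self):
        """>= 95% of well-formed synthetic tRNAs (stems >= 80% WC) fold back
        to their planted per-arm pair-class census."""
        rng = np.random.default_rng(424242)
        ok = tot = 0
        for _ in range(120):
            length = int(rng.integers(66, 78))
            gu = {}
            for arm, k in zip(ARMS, rng.multinomial(int(rng.integers(0, 3)),
                                                    [0.25] * 4)):
                if k:
                    gu[arm] = int(k)
            try:
                seq, layout, _ = make_trna(length, "GAA", gu, rng)
            except Exception:
                continue  # plan exceeded an interior-stem capacity
            fold = fold_cloverleaf(seq, anticodon="GAA")
            planted = {a: gu.get(a, 0) for a in ARMS}
            found = {a: fold.arm_census(a)["non_WC"] for a in ARMS}
            tot += 1
            ok += planted == found
        assert tot >= 100
        assert ok / tot >= 0.95


class TestCensus:
    def test_empty_list_gives_zeros(self):
        census = mismatch_census([])
        assert all(census[arm] == {"GU": 0, "other": 0, "non_WC": 0}
                   for arm in ARMS)
        assert census["total"] == {"GU": 0, "other": 0, "non_WC": 0}

    def test_planted_counts_recovered_exactly(self):
        rng = np.random.default_rng(77)
        plan = [{"dhu": 1}, {"acceptor": 2}, {"tpsic": 1, "anticodon": 1}]
        folds = []
        for i, gu in enumerate(plan):
            seq, *_ = make_trna(70 + i, "GAA", gu, rng)
            folds.append(fold_cloverleaf(seq, anticodon="GAA"))
        census = mismatch_census(folds)
        assert census["acceptor"]["GU"] == 2
        assert census["dhu"]["GU"] == 1
        assert census["anticodon"]["GU"] == 1
        assert census["tpsic"]["GU"] == 1
        assert census["total"] == {"GU": 5, "other": 0, "non_WC": 5}

    def test_total_equals_sum_of_arms(self, synthetic_bundle):
        genome, feats, _ = synthetic_bundle
        folds = [fold_feature(genome, f) for f in feats
                 if f.feature_class == "tRNA"]
        census = mismatch_census(folds)
        for key in ("GU", "other", "non_WC"):
            assert census["total"][key] == sum(census[a][key] for a in ARMS)

    def test_default_template_plants_24_wobble_pairs(self, synthetic_bundle):
        """The default synthetic genome carries the study-design census:
        24 non-WC pairs across 22 tRNAs (8/6/3/7 per arm)."""
        _, _, truth = synthetic_bundle
        planted = {arm: sum(c[arm]["GU"] + c[arm]["other"]
                            for c in truth.trna_arm_census.values())
                   for arm in ARMS}
        assert sum(planted.values()) == 24
        assert planted == {"acceptor": 8, "dhu": 6, "anticodon": 3, "tpsic": 7}
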