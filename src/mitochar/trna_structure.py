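"""Template-based tRNA cloverleaf folding and base-pair census.

A tRNA gene is folded onto the canonical cloverleaf: acceptor (amino-acid)
stem, DHU arm, anticodon arm, variable loop, and TΨC arm.  Rather than
thermodynamic folding, the fold is an exhaustive search over all template
placements within canonical bounds (acceptor stem 6–7 pairs, DHU stem 3–4,
anticodon stem 4–5 with a 7-nt loop centred on the anticodon, TΨC stem 4–5,
variable loop 3–23 nt), scored +2 per Watson–Crick pair, +1 per G·U wobble
pair, −1 per any other apposition.  The argmax placement is returned;
tie-break is fully deterministic (most WC+G·U pairs, then shortest variable
loop, then leftmost acceptor start, then lexicographic layout).

Published mitogenome descriptions call every non-WC pair a "mismatch"; the
census therefore reports all non-WC pairs, subclassing G·U wobbles.
Sequences are DNA as annotated, so the G·U wobble appears as G/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FeatureValidationError, NoCloverleafError
from .io_genbank import CircularGenome, GeneFeature

ARMS = ("acceptor", "dhu", "anticodon", "tpsic")

WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
GU_PAIRS = frozenset({("G", "T"), ("T", "G")})

PAIR_SCORES = {"WC": 2, "GU": 1, "mismatch": -1}
MIN_PAIRED = 15          # minimum WC+GU pairs for a credible cloverleaf

# template bounds (stem lengths in pairs, loops/linkers in nt)
ACC_RANGE = (6, 7)
C1_RANGE = (1, 2, 3)     # acceptor→DHU linker
D_RANGE = (3, 4)
DLOOP_RANGE = range(4, 13)
C2_RANGE = (0, 1, 2)     # DHU→anticodon linker
AC_RANGE = (4, 5)
AC_LOOP = 7              # anticodon loop, anticodon at its centre
VLOOP_MIN, VLOOP_MAX = 3, 23
T_RANGE = (4, 5)
TLOOP_RANGE = range(5, 10)
TAIL_RANGE = range(0, 5)  # discriminator (+ partial CCA)
LEAD_RANGE = (0, 1)


def pair_class(x: str, y: str) -> str:
    """Classify an apposed base pair: 'WC', 'GU' or 'mismatch'."""
    p = (x, y)
    if p in WC_PAIRS:
        return "WC"
    if p in GU_PAIRS:
        return "GU"
    return "mismatch"


@dataclass(frozen=True)
class Layout:
    """One cloverleaf template placement (all lengths in nt / pairs)."""

    lead: int
    acc: int
    c1: int
    d: int
    dloop: int
    c2: int
    ac: int
    vloop: int
    t: int
    tloop: int
    tail: int

    @property
    def length(self) -> int:
        return (self.lead + 2 * self.acc + self.c1 + 2 * self.d + self.dloop
                + self.c2 + 2 * self.ac + AC_LOOP + self.vloop
                + 2 * self.t + self.tloop + self.tail)

    def stem_positions(self) -> dict[str, list[tuple[int, int]]]:
        """0-based (five', three') apposed positions per arm."""
        i_d5 = self.lead + self.acc + self.c1
        i_d3 = i_d5 + self.d + self.dloop
        i_ac5 = i_d3 + self.d + self.c2
        loop = i_ac5 + self.ac
        i_ac3 = loop + AC_LOOP
        i_t5 = i_ac3 + self.ac + self.vloop
        i_t3 = i_t5 + self.t + self.tloop
        i_acc3 = i_t3 + self.t
        mk = lambda i, j, L: [(i + k, j + L - 1 - k) for k in range(L)]
        return {
            "acceptor": mk(self.lead, i_acc3, self.acc),
            "dhu": mk(i_d5, i_d3, self.d),
            "anticodon": mk(i_ac5, i_ac3, self.ac),
            "tpsic": mk(i_t5, i_t3, self.t),
        }

    @property
    def anticodon_start(self) -> int:
        """0-based start of the anticodon triplet (loop centre)."""
        i_d5 = self.lead + self.acc + self.c1
        i_ac5 = i_d5 + 2 * self.d + self.dloop + self.c2
        return i_ac5 + self.ac + 2


@dataclass
class CloverleafFold:
    """Arm-resolved base-pair classification of one folded tRNA."""

    trna: str
    seq: str
    layout: Layout
    #: per arm: list of (pos5, pos3, pair_class) with 1-based positions
    arms: dict[str, list[tuple[int, int, str]]]
    anticodon_triplet: str
    fold_score: int

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.arms.values())

    @property
    def n_paired(self) -> int:
        """WC + G·U pairs actually formed."""
        return sum(1 for v in self.arms.values() for *_, c in v if c != "mismatch")

    def arm_census(self, arm: str) -> dict[str, int]:
        gu = sum(1 for *_, c in self.arms[arm] if c == "GU")
        other = sum(1 for *_, c in self.arms[arm] if c == "mismatch")
        return {"GU": gu, "other": other, "non_WC": gu + other}

    def dot_bracket(self) -> str:
        """Dot-bracket string ('(' 5' side, ')' 3' side, '.' unpaired);
        mismatched appositions are left unpaired in the string."""
        chars = ["."] * len(self.seq)
        for pairs in self.arms.values():
            for p5, p3, cls in pairs:
                if cls != "mismatch":
                    chars[p5 - 1] = "("
                    chars[p3 - 1] = ")"
        return "".join(chars)


def _stem_eval(seq: str, i: int, j: int, L: int):
    """Score + classes of pairing seq[i+k] against seq[j+L-1-k]."""
    score = 0
    paired = 0
    classes = []
    for k in range(L):
        c = pair_class(seq[i + k], seq[j + L - 1 - k])
        score += PAIR_SCORES[c]
        if c != "mismatch":
            paired += 1
        classes.append(c)
    return score, paired, classes


def fold_cloverleaf(seq: str,
                    anticodon: Optional[str] = None,
                    trna: str = "tRNA") -> CloverleafFold:
    """Fold a tRNA sequence by exhaustive cloverleaf-template search.

    When ``anticodon`` is given, placements are first restricted to those
    centring it in the anticodon loop; if none exists the search falls back
    to the unconstrained template space.  Raises
    :class:`~mitochar.errors.NoCloverleafError` if no placement forms at
    least ``MIN_PAIRED`` WC/G·U pairs.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if not 55 <= n <= 95:
        raise FeatureValidationError(
            f"{trna}: tRNA length must be in [55, 95] nt, got {n}"
        )
    anticodon_dna = anticodon.upper().replace("U", "T") if anticodon else None

    best = _search(seq, n, anticodon_dna)
    if best is None and anticodon_dna is not None:
        best = _search(seq, n, None)
    if best is None:
        raise NoCloverleafError(
            f"{trna}: no template placement with >= {MIN_PAIRED} WC/GU pairs"
        )
    _, layout = best
    positions = layout.stem_positions()
    arms = {
        arm: [(p5 + 1, p3 + 1, pair_class(seq[p5], seq[p3])) for p5, p3 in pos]
        for arm, pos in positions.items()
    }
    score = sum(PAIR_SCORES[c] for v in arms.values() for *_, c in v)
    a0 = layout.anticodon_start
    return CloverleafFold(trna=trna, seq=seq, layout=layout, arms=arms,
                          anticodon_triplet=seq[a0:a0 + 3], fold_score=score)


def _search(seq: str, n: int, anticodon_dna: Optional[str]):
    """Return (sort_key, Layout) of the best placement, or None."""
    cache: dict[tuple[int, int, int], tuple[int, int]] = {}

    def stem(i, j, L):
        key = (i, j, L)
        hit = cache.get(key)
        if hit is None:
            s, p, _ = _stem_eval(seq, i, j, L)
            hit = cache[key] = (s, p)
        return hit

    best = None
    for lead in LEAD_RANGE:
        for acc in ACC_RANGE:
            rights = []
            for tail in TAIL_RANGE:
                i_acc3 = n - tail - acc
                s_acc, p_acc = stem(lead, i_acc3, acc)
                for t in T_RANGE:
                    for tloop in TLOOP_RANGE:
                        i_t3 = i_acc3 - t
                        i_t5 = i_t3 - tloop - t
                        if i_t5 < 0:
                            continue
                        s_t, p_t = stem(i_t5, i_t3, t)
                        rights.append((i_t5, s_acc + s_t, p_acc + p_t,
                                       tail, t, tloop))
            for c1 in C1_RANGE:
                i_d5 = lead + acc + c1
                for d in D_RANGE:
                    for dloop in DLOOP_RANGE:
                        i_d3 = i_d5 + d + dloop
                        if i_d3 + d >= n:
                            continue
                        s_d, p_d = stem(i_d5, i_d3, d)
                        for c2 in C2_RANGE:
                            i_ac5 = i_d3 + d + c2
                            for ac in AC_RANGE:
                                loop = i_ac5 + ac
                                i_ac3 = loop + AC_LOOP
                                if i_ac3 + ac >= n:
                                    continue
                                if (anticodon_dna is not None
                                        and seq[loop + 2:loop + 5] != anticodon_dna):
                                    continue
                                s_ac, p_ac = stem(i_ac5, i_ac3, ac)
                                left_end = i_ac3 + ac
                                s_left = s_d + s_ac
                                p_left = p_d + p_ac
                                for (i_t5, s_right, p_right,
                                     tail, t, tloop) in rights:
                                    vloop = i_t5 - left_end
                                    if not VLOOP_MIN <= vloop <= VLOOP_MAX:
                                        continue
                                    paired = p_left + p_right
                                    if paired < MIN_PAIRED:
                                        continue
                                    score = s_left + s_right
                                    key = (-score, -paired, vloop, lead, acc,
                                           c1, d, dloop, c2, ac, t, tloop, tail)
                                    if best is None or key < best[0]:
                                        best = (key, Layout(
                                            lead=lead, acc=acc, c1=c1, d=d,
                                            dloop=dloop, c2=c2, ac=ac,
                                            vloop=vloop, t=t, tloop=tloop,
                                            tail=tail))
    return best


def fold_feature(genome: CircularGenome, feature: GeneFeature) -> CloverleafFold:
    """Fold an annotated tRNA gene (sense strand, annotated anticodon)."""
    return fold_cloverleaf(feature.sense_sequence(genome),
                           anticodon=feature.anticodon, trna=feature.name)


def mismatch_census(folds: Iterable[CloverleafFold]) -> dict:
    """Per-arm and overall counts of G·U and other non-WC pairs."""
    census = {arm: {"GU": 0, "other": 0, "non_WC": 0} for arm in ARMS}
    for fold in folds:
        for arm in ARMS:
            c = fold.arm_census(arm)
            for k in census[arm]:
                census[arm][k] += c[k]
    census["total"] = {
        k: sum(census[arm][k] for arm in ARMS) for k in ("GU", "other", "non_WC")
    }
    return census
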