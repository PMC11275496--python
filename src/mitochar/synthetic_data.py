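"""Synthetic circular mitogenomes with fully known ground truth.

The generator emits a 37-gene vertebrate-style circular mitogenome from a
declarative :class:`GenomeSpec`: gene order/lengths/strands, planted
overlaps and spacers (as inter-gene offsets), base composition of
non-coding sequence, a 64-codon sampling weight vector for PCGs, planted
start/stop codons (including the incomplete ``TA-``/``T--`` types), and
per-arm planted G·U pairs in template-built cloverleaf tRNAs.

The default spec mirrors the published annotation of the Myophonus
caeruleus mitogenome (GenBank MN564936): its exact gene order and
coordinates (hence 9 overlaps / 32 bp, 22 spacers, 7 adjacencies on a
16,815 bp circle), its start/stop codon typing, its whole-genome base
frequencies, its published codon counts as sampling weights, and 24 G·U
pairs distributed over the arms as in its tRNA census (8 acceptor, 6 DHU,
3 anticodon, 7 TΨC).

Features are written onto the background sequence in start order
(tRNAs in a final pass so their stems win overlap conflicts); the
:class:`TruthRecord` is then re-derived from the *emitted* sequence by
deliberately simple tallies (character counts, triplet slicing, planted
stem positions), so truth always describes the genome actually returned,
including any planted values perturbed inside overlap regions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import datasets
from .codon_usage import MITO_STOPS, to_rna
from .errors import SpecValidationError
from .genome_stats import at_skew, gc_skew
from .io_genbank import (
    CONTROL_REGION, PCG, RRNA, TRNA,
    CircularGenome, GeneFeature, revcomp, sort_features,
)
from .trna_structure import ARMS, Layout

_BASES = np.array(list("ACGT"))

TRNA_MIN_LEN, TRNA_MAX_LEN = 66, 88


def _trna_layout(length: int) -> Layout:
    """Generator cloverleaf geometry for a given gene length.

    Stems are at the template maxima (acceptor 7, DHU 4, anticodon 5,
    TΨC 5) so the planted placement dominates every shorter alternative;
    the variable loop absorbs the length difference, with a 3-pair DHU
    stem for the two shortest lengths.
    """
    if not TRNA_MIN_LEN <= length <= TRNA_MAX_LEN:
        raise SpecValidationError(
            f"tRNA length {length} outside the template range "
            f"[{TRNA_MIN_LEN}, {TRNA_MAX_LEN}]"
        )
    d = 4 if length >= 68 else 3
    fixed = 65 if d == 4 else 63
    return Layout(lead=0, acc=7, c1=2, d=d, dloop=5, c2=1, ac=5,
                  vloop=length - fixed, t=5, tloop=7, tail=1)

_SENSE_CODONS = tuple(c for c in
                      (a + b + d for a in "TCAG" for b in "TCAG" for d in "TCAG")
                      if c not in MITO_STOPS)


@dataclass
class GeneTemplate:
    name: str
    feature_class: str
    strand: str
    length: int
    anticodon: Optional[str] = None


@dataclass
class GenomeSpec:
    """Declarative recipe for one synthetic circular mitogenome."""

    seed: int
    gene_order: list[GeneTemplate]
    #: offset between consecutive genes: negative = overlap bp, 0 = exact
    #: adjacency, positive = spacer bp (len(gene_order) - 1 entries)
    offsets: list[int]
    #: spacer closing the circle from the last gene back to the first
    closing_gap: int
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    #: 64-codon sampling weights (RNA or DNA keys); None = uniform over the
    #: 60 non-stop codons of the vertebrate mito code
    codon_weights: Optional[dict[str, float]] = None
    start_plan: dict[str, str] = field(default_factory=dict)
    stop_plan: dict[str, str] = field(default_factory=dict)
    #: per-tRNA planted G·U wobble pairs per arm, e.g. {"trnF": {"dhu": 1}}
    trna_plan: dict[str, dict[str, int]] = field(default_factory=dict)
    id: str = "synthetic"

    @property
    def genome_length(self) -> int:
        return (sum(g.length for g in self.gene_order) + sum(self.offsets)
                + self.closing_gap)

    def validate(self) -> None:
        genes = self.gene_order
        if not genes:
            raise SpecValidationError("gene_order is empty")
        if len(self.offsets) != len(genes) - 1:
            raise SpecValidationError(
                f"need {len(genes) - 1} offsets, got {len(self.offsets)}"
            )
        if self.closing_gap < 0:
            raise SpecValidationError("closing_gap must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise SpecValidationError("base_freqs must sum to 1")
        for i, off in enumerate(self.offsets):
            if off < 0 and -off >= min(genes[i].length, genes[i + 1].length):
                raise SpecValidationError(
                    f"overlap {-off} bp at pair {i} exceeds a gene length"
                )
        for g in genes:
            if g.feature_class == TRNA:
                _trna_layout(g.length)  # raises if outside the template range
            if g.feature_class == PCG:
                stop = self.stop_plan.get(g.name, "TAA")
                rem = {"TA-": 2, "T--": 1}.get(stop, 0)
                if stop not in ("TA-", "T--") and stop not in MITO_STOPS:
                    raise SpecValidationError(f"{g.name}: unknown stop {stop!r}")
                if g.length % 3 != rem:
                    raise SpecValidationError(
                        f"{g.name}: length {g.length} % 3 == {g.length % 3} "
                        f"inconsistent with stop {stop!r}"
                    )
                if g.length < 9:
                    raise SpecValidationError(f"{g.name}: PCG too short")

    def coordinates(self) -> list[tuple[int, int]]:
        spans = []
        start = 1
        for i, g in enumerate(self.gene_order):
            end = start + g.length - 1
            spans.append((start, end))
            if i < len(self.offsets):
                start = end + 1 + self.offsets[i]
        return spans


@dataclass
class TruthRecord:
    """Every plantable quantity, re-derived from the emitted sequence."""

    seed: int
    genome_length: int
    base_counts: dict[str, int]
    at_skew: float
    gc_skew: float
    overlap_count: int
    overlap_bp: int
    spacer_count: int
    spacer_bp: int
    adjacency_count: int
    strand_counts: dict[str, int]
    class_lengths: dict[str, int]
    start_codons: dict[str, str]
    stop_codons: dict[str, Optional[str]]
    codon_counts: dict[str, int]
    trna_layouts: dict[str, Layout]
    #: per-tRNA per-arm {"GU": n, "other": n} classified on the final sequence
    trna_arm_census: dict[str, dict[str, dict[str, int]]]


def default_spec(seed: int = 0) -> GenomeSpec:
    """The MN564936-template spec (gene order, codons, skews, G·U census)."""
    feats = datasets.reference_features()
    order, offsets = [], []
    for i, f in enumerate(feats):
        order.append(GeneTemplate(name=f.name, feature_class=f.feature_class,
                                  strand=f.strand, length=f.length,
                                  anticodon=f.anticodon))
        if i + 1 < len(feats):
            offsets.append(feats[i + 1].start - f.end - 1)
    closing = datasets.MN564936_LENGTH - feats[-1].end + feats[0].start - 1
    weights = {k: float(v) for k, v in datasets.reference_codon_counts().items()}
    trnas = [g.name for g in order if g.feature_class == TRNA]
    plan: dict[str, dict[str, int]] = {t: {} for t in trnas}
    arm_quota = {"acceptor": 8, "dhu": 6, "tpsic": 7, "anticodon": 3}
    slot = 0
    for arm in ARMS:
        for _ in range(arm_quota.get(arm, 0)):
            t = trnas[slot % len(trnas)]
            plan[t][arm] = plan[t].get(arm, 0) + 1
            slot += 1
    return GenomeSpec(
        seed=seed, gene_order=order, offsets=offsets, closing_gap=closing,
        base_freqs=(0.3006, 0.3145, 0.1478, 0.2371),
        codon_weights=weights,
        start_plan=dict(datasets.MN564936_START_CODONS),
        stop_plan=dict(datasets.MN564936_STOP_CODONS),
        trna_plan=plan, id="synthetic-mn564936-template",
    )


# ---------------------------------------------------------------------------
# sequence builders
# ---------------------------------------------------------------------------

def _random_bases(rng, n, freqs) -> str:
    return "".join(rng.choice(_BASES, size=n, p=list(freqs)))


def make_trna(length: int, anticodon: str, gu_per_arm: dict[str, int],
              rng: np.random.Generator) -> tuple[str, Layout, dict[str, list[str]]]:
    """Build one cloverleaf tRNA: WC stems except planted G·U pairs.

    Returns the DNA sequence, its generating :class:`Layout`, and the
    planted pair classes per arm.
    """
    layout = _trna_layout(length)
    assert layout.length == length
    # loops/linkers are A/C-only (unpairable against each other) and stem
    # boundaries carry A.A blocker appositions, so no alternative template
    # placement can match the planted stems' score: the planted layout is
    # the identifiable argmax of the fold search
    chars = [str(b) for b in rng.choice(np.array(["A", "C"]), size=length)]
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    positions = layout.stem_positions()
    classes: dict[str, list[str]] = {}
    for arm in ARMS:
        pairs = positions[arm]
        k = gu_per_arm.get(arm, 0)
        interior = list(range(1, len(pairs) - 1)) or [0]
        if k > len(interior):
            raise SpecValidationError(
                f"cannot plant {k} GU pairs inside a {len(pairs)}-pair {arm} stem"
            )
        gu_idx = set(rng.choice(interior, size=k, replace=False)) if k else set()
        prev: list[str] = []
        classes[arm] = []
        for idx, (p5, p3) in enumerate(pairs):
            if idx in gu_idx:
                b = "G"
                chars[p5], chars[p3] = "G", "T"
                classes[arm].append("GU")
            else:
                # no base repeats within distance 2 along the 5' strand, so
                # stems shifted by 1-2 nt always cross-pair to a mismatch
                allowed = [b for b in "ACGT" if b not in prev[-2:]]
                b = str(rng.choice(np.array(allowed)))
                chars[p5], chars[p3] = b, comp[b]
                classes[arm].append("WC")
            prev.append(b)
    i_d5 = layout.lead + layout.acc + layout.c1
    i_d3 = i_d5 + layout.d + layout.dloop
    i_ac3 = i_d3 + layout.d + layout.c2 + layout.ac + 7
    i_t5 = i_ac3 + layout.ac + layout.vloop
    i_t3 = i_t5 + layout.t + layout.tloop
    for pos in (i_d5 + layout.d, i_d3 - 1,          # D-loop edges
                i_t5 + layout.t, i_t3 - 1,          # T-loop edges
                i_d5 - 1,                           # last linker base before D stem
                i_d3 + layout.d,                    # linker base after D stem
                i_ac3 + layout.ac,                  # first variable-loop base
                i_t5 - 1):                          # last variable-loop base
        chars[pos] = "A"
    a0 = layout.anticodon_start
    chars[a0:a0 + 3] = list(anticodon.upper().replace("U", "T"))
    return "".join(chars), layout, classes


def make_pcg(length: int, start: str, stop: str,
             weights: Optional[dict[str, float]],
             rng: np.random.Generator) -> str:
    """Sense-strand PCG: planted start, sampled sense codons, planted stop."""
    rem = {"TA-": 2, "T--": 1}.get(stop, 0)
    n_cod = (length - rem) // 3
    if weights is None:
        p = np.full(len(_SENSE_CODONS), 1.0 / len(_SENSE_CODONS))
    else:
        w = {c.upper().replace("U", "T"): float(v) for c, v in weights.items()}
        raw = np.array([max(w.get(c, 0.0), 0.0) for c in _SENSE_CODONS])
        if raw.sum() <= 0:
            raise SpecValidationError("codon_weights give zero mass to sense codons")
        p = raw / raw.sum()
    body_n = n_cod - 1 - (0 if rem else 1)
    codons = [start.upper()]
    codons += list(rng.choice(np.array(_SENSE_CODONS), size=body_n, p=p))
    tail = {"TA-": "TA", "T--": "T"}.get(stop, stop.upper())
    if rem == 0:
        codons.append(tail)
        return "".join(codons)
    return "".join(codons) + tail


def generate(spec: GenomeSpec) -> tuple[CircularGenome, list[GeneFeature], TruthRecord]:
    """Emit a genome + features + truth; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G = spec.genome_length
    spans = spec.coordinates()
    arr = np.array(list(_random_bases(rng, G, spec.base_freqs)))

    features: list[GeneFeature] = []
    trna_layouts: dict[str, Layout] = {}
    trna_classes: dict[str, dict[str, list[str]]] = {}
    writes = []  # (pass_rank, start, genome-strand seq)
    for g, (start, end) in zip(spec.gene_order, spans):
        anticodon = g.anticodon
        if g.feature_class == TRNA:
            if anticodon is None:
                anticodon = "".join(rng.choice(_BASES, size=3))
            sense, layout, classes = make_trna(g.length, anticodon,
                                               spec.trna_plan.get(g.name, {}),
                                               rng)
            trna_layouts[g.name] = layout
            trna_classes[g.name] = classes
            rank = 1  # tRNAs written last: stems win overlap conflicts
        elif g.feature_class == PCG:
            sense = make_pcg(g.length, spec.start_plan.get(g.name, "ATG"),
                             spec.stop_plan.get(g.name, "TAA"),
                             spec.codon_weights, rng)
            rank = 0
        else:  # rRNA / control region: plain background composition
            sense = _random_bases(rng, g.length, spec.base_freqs)
            rank = 0
        genome_strand = revcomp(sense) if g.strand == "L" else sense
        writes.append((rank, start, genome_strand))
        features.append(GeneFeature(name=g.name, feature_class=g.feature_class,
                                    strand=g.strand, start=start, end=end,
                                    anticodon=anticodon))
    for rank in (0, 1):
        for r, start, s in writes:
            if r == rank:
                arr[start - 1:start - 1 + len(s)] = list(s)

    _repair_trna_stems(arr, spec, spans, trna_layouts, trna_classes)
    seq = "".join(arr)
    genome = CircularGenome(id=spec.id, length=G, seq=seq, circular=True)
    features = sort_features(features)
    truth = _derive_truth(spec, genome, features, trna_layouts)
    return genome, features, truth


_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def _repair_trna_stems(arr, spec, spans, trna_layouts, trna_classes) -> None:
    """Restore tRNA stem pairs broken by overlap overwrites.

    When two annotated genes share a few bp (e.g. two tRNAs abutting with a
    1-bp overlap), the later write wins the shared positions and can break
    the earlier tRNA's terminal stem pair.  As in real overlapping tRNAs,
    the shared base serves both genes and the *unshared* partner base is
    chosen to complement it, so every planted stem pair is present in the
    emitted sequence.
    """
    coverage: dict[int, int] = {}
    for s, e in spans:
        for p in range(s, e + 1):
            coverage[p] = coverage.get(p, 0) + 1
    shared = {p for p, c in coverage.items() if c > 1}

    by_name = {g.name: (g, span) for g, span in zip(spec.gene_order, spans)}
    for name, layout in trna_layouts.items():
        g, (start, end) = by_name[name]
        to_genome = (lambda i: start + i) if g.strand == "H" else (lambda i: end - i)
        read = (lambda p: arr[p - 1]) if g.strand == "H" \
            else (lambda p: _COMP[arr[p - 1]])
        positions = layout.stem_positions()
        for arm in ARMS:
            for (p5, p3), planted in zip(positions[arm], trna_classes[name][arm]):
                if planted != "WC":
                    continue
                g5, g3 = to_genome(p5), to_genome(p3)
                b5, b3 = read(g5), read(g3)
                if _COMP[b5] == b3:
                    continue
                if g5 in shared and g3 not in shared:
                    fix, sense = g3, _COMP[b5]
                elif g3 in shared and g5 not in shared:
                    fix, sense = g5, _COMP[b3]
                else:
                    continue
                arr[fix - 1] = sense if g.strand == "H" else _COMP[sense]


def _derive_truth(spec, genome, features, trna_layouts) -> TruthRecord:
    """Re-derive all plantable quantities from the emitted sequence with
    deliberately naive tallies (independent of the analysis modules)."""
    seq = genome.seq
    counts = {b: seq.count(b) for b in "ACGTN"}

    ov_n = ov_bp = sp_n = sp_bp = adj = 0
    for off in list(spec.offsets) + [spec.closing_gap]:
        if off < 0:
            ov_n, ov_bp = ov_n + 1, ov_bp - off
        elif off > 0:
            sp_n, sp_bp = sp_n + 1, sp_bp + off
        else:
            adj += 1

    by_name = {f.name: f for f in features}
    starts, stops, codon_counts = {}, {}, Counter()
    for g in spec.gene_order:
        if g.feature_class != PCG:
            continue
        f = by_name[g.name]
        s = f.sense_sequence(genome)
        rem = len(s) % 3
        if rem == 1:
            stops[g.name] = "T--" if s[-1] == "T" else None
        elif rem == 2:
            stops[g.name] = "TA-" if s[-2:] == "TA" else None
        else:
            stops[g.name] = s[-3:] if s[-3:] in MITO_STOPS else None
        body = s[:len(s) - rem]
        starts[g.name] = body[:3]
        for i in range(0, len(body), 3):
            codon_counts[to_rna(body[i:i + 3])] += 1

    arm_census: dict[str, dict[str, dict[str, int]]] = {}
    for g in spec.gene_order:
        if g.feature_class != TRNA:
            continue
        s = by_name[g.name].sense_sequence(genome)
        layout = trna_layouts[g.name]
        census = {}
        for arm, pairs in layout.stem_positions().items():
            gu = other = 0
            for p5, p3 in pairs:
                pair = (s[p5], s[p3])
                if pair in (("G", "T"), ("T", "G")):
                    gu += 1
                elif pair not in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
                    other += 1
            census[arm] = {"GU": gu, "other": other}
        arm_census[g.name] = census

    class_lengths: dict[str, int] = {}
    strand_counts = {"H": 0, "L": 0}
    for f in features:
        class_lengths[f.feature_class] = class_lengths.get(f.feature_class, 0) + f.length
        strand_counts[f.strand] += 1

    return TruthRecord(
        seed=spec.seed, genome_length=genome.length, base_counts=counts,
        at_skew=at_skew(counts["A"], counts["T"]),
        gc_skew=gc_skew(counts["G"], counts["C"]),
        overlap_count=ov_n, overlap_bp=ov_bp,
        spacer_count=sp_n, spacer_bp=sp_bp, adjacency_count=adj,
        strand_counts=strand_counts, class_lengths=class_lengths,
        start_codons=starts, stop_codons=stops,
        codon_counts=dict(codon_counts),
        trna_layouts=trna_layouts, trna_arm_census=arm_census,
    )


# ---------------------------------------------------------------------------
# multi-taxon sets and coordinate rotation
# ---------------------------------------------------------------------------

def generate_taxa(spec: GenomeSpec, n_taxa: int, per_site_sub_rate: float,
                  taxon_names: Optional[list[str]] = None):
    """Derive ``n_taxa`` genomes from one root by i.i.d. substitutions.

    Indel-free, so per-gene sequences stay length-matched across taxa.
    Returns ``(taxon_genes, root_genome, features)`` where ``taxon_genes``
    maps taxon -> {PCG id -> sense sequence} ready for supermatrix building.
    """
    if not 0 <= per_site_sub_rate <= 0.3:
        raise SpecValidationError("per_site_sub_rate must be in [0, 0.3]")
    genome, features, _ = generate(spec)
    rng = np.random.default_rng(spec.seed + 1)
    names = taxon_names or [f"taxon_{i:02d}" for i in range(n_taxa)]
    if len(names) != n_taxa:
        raise SpecValidationError("taxon_names length != n_taxa")
    root = np.array(list(genome.seq))
    out = {}
    for name in names:
        mut = root.copy()
        hit = rng.random(len(mut)) < per_site_sub_rate
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = [b for b in "ACGT" if b != mut[i]]
            mut[i] = choices[rng.integers(3)]
        g = CircularGenome(id=name, length=genome.length, seq="".join(mut))
        out[name] = {f.name: f.sense_sequence(g)
                     for f in features if f.feature_class == PCG}
    return out, genome, features


def rotate_origin(genome: CircularGenome, features: list[GeneFeature],
                  offset: int) -> tuple[CircularGenome, list[GeneFeature]]:
    """Rotate the circular origin by ``offset`` bp (old position offset+1
    becomes position 1); origin-spanning features are split into two parts."""
    G = genome.length
    offset %= G
    seq = None
    if genome.has_sequence:
        seq = genome.seq[offset:] + genome.seq[:offset]
    rotated: list[GeneFeature] = []
    for f in features:
        s = (f.start - 1 - offset) % G + 1
        e = (f.end - 1 - offset) % G + 1
        if s <= e:
            rotated.append(GeneFeature(name=f.name, feature_class=f.feature_class,
                                       strand=f.strand, start=s, end=e,
                                       anticodon=f.anticodon, mapped=f.mapped))
        else:  # now spans the origin: split
            for part, (ps, pe) in enumerate(((s, G), (1, e)), start=1):
                rotated.append(GeneFeature(name=f.name, feature_class=f.feature_class,
                                           strand=f.strand, start=ps, end=pe,
                                           anticodon=f.anticodon, mapped=f.mapped,
                                           part=part))
    g2 = CircularGenome(id=genome.id + f"|rot{offset}", length=G, seq=seq,
                        circular=True)
    return g2, sort_features(rotated)
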