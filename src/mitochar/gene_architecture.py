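"""Circular gene-order analytics: overlaps, spacers, adjacencies, class totals.

Vertebrate mitogenomes are gene-dense: neighbouring genes overlap by a few
bp (e.g. atp8/atp6 share 10 bp), abut exactly, or are separated by short
intergenic spacers.  This module accounts for all three relations along the
single mixed-strand circular gene order, closes the circle through the
origin using the *declared* genome length, and reports per-class length
totals.

Two complementary overlap/spacer definitions are used:

* pairwise — each consecutive pair ``(a, b)`` in start order contributes
  ``a.end − b.start + 1`` bp of overlap (if positive), ``b.start − a.end − 1``
  bp of spacer (if positive), or one exact adjacency;
* occupancy — total overlap bp is the coverage excess
  ``Σ lengths − covered positions`` and total spacer bp the number of
  uncovered positions.

The two agree whenever no feature is nested inside another (the usual
case); with nesting, the report totals follow the occupancy definition so
the circular length-conservation identity
``Σ lengths − overlap_bp + spacer_bp == genome_length`` always holds, and
nested pairs are additionally flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import FeatureValidationError
from .io_genbank import GeneFeature, sort_features


@dataclass
class ArchitectureReport:
    """Overlap/spacer/adjacency accounting for one circular annotation."""

    genome_length: int
    circular: bool
    overlaps: list[tuple[str, str, int]]
    spacers: list[tuple[str, str, int]]
    adjacencies: list[tuple[str, str]]
    overlap_bp: int
    spacer_bp: int
    strand_inventory: dict
    class_lengths: dict
    nested: list[tuple[str, str]] = field(default_factory=list)
    #: the through-origin closing interval (pair, bp), if it is a spacer
    closing_spacer: Optional[tuple[str, str, int]] = None

    @property
    def overlap_count(self) -> int:
        return len(self.overlaps)

    @property
    def spacer_count(self) -> int:
        return len(self.spacers)

    @property
    def adjacency_count(self) -> int:
        return len(self.adjacencies)

    @property
    def annotated_span(self) -> int:
        """Last annotated coordinate (basis for 'fraction of mitochondrial
        genes' style percentages)."""
        return self._last_end

    _last_end: int = 0

    def spacer_fractions(self) -> dict[str, float]:
        """Spacer total as a fraction of the genome and of the annotated span."""
        return {
            "of_genome_length": self.spacer_bp / self.genome_length,
            "of_annotated_span": self.spacer_bp / self._last_end if self._last_end else float("nan"),
        }

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "genome_length": self.genome_length,
            "circular": self.circular,
            "overlaps": [list(t) for t in self.overlaps],
            "spacers": [list(t) for t in self.spacers],
            "adjacencies": [list(t) for t in self.adjacencies],
            "totals": {
                "overlap_bp": self.overlap_bp,
                "overlap_count": self.overlap_count,
                "spacer_bp": self.spacer_bp,
                "spacer_count": self.spacer_count,
                "adjacency_count": self.adjacency_count,
            },
            "closing_spacer": list(self.closing_spacer) if self.closing_spacer else None,
            "nested": [list(t) for t in self.nested],
            "strand_inventory": self.strand_inventory,
            "class_lengths": self.class_lengths,
        }


def _covered_positions(genome_length: int, features: list[GeneFeature]) -> int:
    """Number of distinct positions covered by >= 1 feature (interval merge)."""
    ivs = sorted((f.start, f.end) for f in features)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e + 1:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s + 1
    return covered


def analyze_architecture(genome_length: int,
                         features: Iterable[GeneFeature],
                         circular: bool = True) -> ArchitectureReport:
    """Classify every consecutive gene pair as overlap / spacer / adjacency.

    Strand is ignored for pairing: the analysis runs on the single
    mixed-strand linear order sorted by start.  On a circular genome the
    pair (last gene, first gene) is closed through the origin with
    ``spacer = genome_length − last.end + first.start − 1``; when the
    annotation stops short of the declared length the unannotated tail is
    thus included in the final circular spacer.
    """
    feats = sort_features(features)
    if not feats:
        raise FeatureValidationError("need at least one feature")
    for f in feats:
        if f.end > genome_length:
            raise FeatureValidationError(
                f"{f.name}: end {f.end} > genome length {genome_length}"
            )

    overlaps, spacers, adjacencies, nested = [], [], [], []
    closing = None
    n = len(feats)
    npairs = n if (circular and n > 1) else n - 1
    for i in range(npairs):
        a, b = feats[i], feats[(i + 1) % n]
        if i < n - 1:
            ov = a.end - b.start + 1
            sp = b.start - a.end - 1
            if b.end <= a.end:  # b nested inside a
                nested.append((a.name, b.name))
        else:  # through-origin closure
            ov = -(genome_length - a.end + b.start - 1)
            sp = genome_length - a.end + b.start - 1
        if ov > 0:
            overlaps.append((a.name, b.name, ov))
        elif sp > 0:
            spacers.append((a.name, b.name, sp))
            if i == n - 1:
                closing = (a.name, b.name, sp)
        else:
            adjacencies.append((a.name, b.name))

    covered = _covered_positions(genome_length, feats)
    total_len = sum(f.length for f in feats)
    overlap_bp = total_len - covered
    spacer_bp = genome_length - covered if circular else sum(s[2] for s in spacers)

    report = ArchitectureReport(
        genome_length=genome_length, circular=circular,
        overlaps=overlaps, spacers=spacers, adjacencies=adjacencies,
        overlap_bp=overlap_bp, spacer_bp=spacer_bp,
        strand_inventory=strand_inventory(feats),
        class_lengths=class_length_summary(genome_length, feats),
        nested=nested, closing_spacer=closing,
    )
    report._last_end = max(f.end for f in feats)
    return report


def strand_inventory(features: Iterable[GeneFeature]) -> dict:
    """Genes per strand with a feature-class breakdown."""
    inv = {"H": {"genes": [], "by_class": {}}, "L": {"genes": [], "by_class": {}}}
    for f in sort_features(features):
        if f.part not in (None, 1):
            continue
        d = inv[f.strand]
        d["genes"].append(f.name)
        d["by_class"][f.feature_class] = d["by_class"].get(f.feature_class, 0) + 1
    for d in inv.values():
        d["count"] = len(d["genes"])
    return inv


def class_length_summary(genome_length: int,
                         features: Iterable[GeneFeature]) -> dict:
    """Per-class total bp (overlaps NOT deduplicated — each gene contributes
    end − start + 1), fraction of the genome, and min/max gene."""
    out: dict[str, dict] = {}
    for f in sort_features(features):
        d = out.setdefault(f.feature_class, {
            "total_bp": 0, "count": 0,
            "min": (None, None), "max": (None, None),
        })
        d["total_bp"] += f.length
        if f.part in (None, 1):
            d["count"] += 1
        if d["min"][1] is None or f.length < d["min"][1]:
            d["min"] = (f.name, f.length)
        if d["max"][1] is None or f.length > d["max"][1]:
            d["max"] = (f.name, f.length)
    for d in out.values():
        d["fraction_of_genome"] = d["total_bp"] / genome_length
    return out
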