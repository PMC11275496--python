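"""Base composition and AT/GC skew statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), the standard
compositional-asymmetry statistics of mitogenome descriptions.  Both are
scale-invariant: counts, fractions or percentages give the same value.
N bases are tallied separately and excluded from skew denominators so the
statistics stay well-defined on draft sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import FeatureValidationError, RegionLookupError, UndefinedSkewError
from .io_genbank import (
    CONTROL_REGION_ID,
    CircularGenome,
    GeneFeature,
    normalize_gene_name,
    revcomp,
)


def at_skew(a_frac: float, t_frac: float) -> float:
    """(A − T)/(A + T); input scale (count/fraction/%) is irrelevant."""
    denom = a_frac + t_frac
    if denom <= 0:
        raise UndefinedSkewError(f"A + T == {denom}; AT-skew undefined")
    return (a_frac - t_frac) / denom


def gc_skew(g_frac: float, c_frac: float) -> float:
    """(G − C)/(G + C); input scale (count/fraction/%) is irrelevant."""
    denom = g_frac + c_frac
    if denom <= 0:
        raise UndefinedSkewError(f"G + C == {denom}; GC-skew undefined")
    return (g_frac - c_frac) / denom


@dataclass
class CompositionProfile:
    """Base counts, percentages and skews for one region.

    Percentages are kept at full precision; rounding happens only in
    :meth:`to_row` / report output.
    """

    region_id: str
    counts: dict[str, int]

    def __post_init__(self):
        for b in "ACGTN":
            self.counts.setdefault(b, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pct(self, base: str) -> float:
        return 100.0 * self.counts[base] / self.total

    @property
    def at_content(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def gc_content(self) -> float:
        return self.pct("G") + self.pct("C")

    @property
    def at_skew(self) -> float:
        return at_skew(self.counts["A"], self.counts["T"])

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.counts["G"], self.counts["C"])

    def to_row(self, precision: int = 2) -> dict:
        """One report row in the conventional composition-table schema."""
        r = lambda x: round(x, precision)
        return {
            "Region": self.region_id,
            "A%": r(self.pct("A")), "C%": r(self.pct("C")),
            "G%": r(self.pct("G")), "T%": r(self.pct("T")),
            "A+T%": r(self.at_content), "G+C%": r(self.gc_content),
            "AT skew": r(self.at_skew), "GC skew": r(self.gc_skew),
        }


def composition(genome: CircularGenome,
                span: Optional[tuple[int, int]] = None,
                strand: str = "H",
                region_id: Optional[str] = None) -> CompositionProfile:
    """Base composition of a span (default: whole genome).

    ``span`` is 1-based inclusive; ``start > end`` wraps through the circular
    origin.  With ``strand == 'L'`` the tally is on the reverse complement,
    i.e. the coding strand of an L-strand gene.
    """
    genome.require_sequence("composition")
    if span is None:
        seq = genome.seq
        region_id = region_id or "Whole genome"
    else:
        start, end = span
        seq = genome.slice(start, end)
        region_id = region_id or f"{start}-{end}"
    if len(seq) == 0:
        raise FeatureValidationError("zero-length span")
    if strand == "L":
        seq = revcomp(seq)
    elif strand != "H":
        raise FeatureValidationError(f"strand must be H or L, got {strand!r}")
    counts = Counter(seq)
    tidy = {b: counts.pop(b, 0) for b in "ACGT"}
    tidy["N"] = sum(counts.values())  # N and any IUPAC ambiguity codes
    return CompositionProfile(region_id=region_id, counts=tidy)


def composition_of_feature(genome: CircularGenome, feature: GeneFeature) -> CompositionProfile:
    """Composition of one gene on its coding (sense) strand."""
    return composition(genome, span=(feature.start, feature.end),
                       strand=feature.strand, region_id=feature.name)


def region_report(genome: CircularGenome,
                  features: Iterable[GeneFeature],
                  regions: Optional[list[str]] = None,
                  precision: int = 2) -> pd.DataFrame:
    """Composition/skew table: whole genome plus the requested regions.

    Region names are resolved through the canonical gene alias table
    (``d-loop`` hits the control region).  Per-gene rows are computed on the
    coding strand.
    """
    features = list(features)
    by_name = {f.name: f for f in features}
    rows = [composition(genome).to_row(precision)]
    for raw in regions or []:
        name = normalize_gene_name(raw)
        if name.lower() in ("whole", "whole genome", "genome"):
            continue
        if name not in by_name:
            if name == CONTROL_REGION_ID and CONTROL_REGION_ID not in by_name:
                raise RegionLookupError("no control region in the annotation")
            raise RegionLookupError(f"unknown region {raw!r}")
        rows.append(composition_of_feature(genome, by_name[name]).to_row(precision))
    return pd.DataFrame(rows)
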