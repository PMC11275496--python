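"""Codon extraction, start/stop typing and relative synonymous codon usage.

Protein-coding genes are read on their sense strand under the vertebrate
mitochondrial genetic code (NCBI transl_table=2), whose stop codons are
TAA, TAG, AGA and AGG.  Genes whose length is not a multiple of three end
in an *incomplete* stop — a trailing ``TA`` (reported ``TA-``) or ``T``
(reported ``T--``) completed to UAA by post-transcriptional
polyadenylation.

RSCU(c) for a codon ``c`` in a synonymous family ``F`` is::

    RSCU(c) = count(c) * |F| / sum over c' in F of count(c')

i.e. the observed count divided by the expectation under uniform use
within the family; the family mean is 1 by construction.

Two family partitions are available.  ``"standard"`` groups codons by
standard-nuclear-code amino acid (Leu 6, Ser 6, Arg 6 including AGA/AGG,
one 3-codon stop family) — the grouping conventionally produced by
codon-usage software and the package default.  ``"mito"`` groups by
transl_table=2 (Arg 4, stops {UAA, UAG, AGA, AGG}, Trp {UGA, UGG},
Met {AUA, AUG}).  Stop/start *typing* always uses the mito code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .errors import FeatureValidationError, SequenceAbsentError
from .io_genbank import PCG, CircularGenome, GeneFeature

logger = logging.getLogger(__name__)

#: stop codons of the vertebrate mitochondrial code (DNA alphabet)
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})
INCOMPLETE_STOPS = ("TA-", "T--")

_BASES = "TCAG"
ALL_CODONS_DNA = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _families_from_table(table_id: int) -> dict[str, tuple[str, ...]]:
    """Synonymous families (RNA keys) grouped by amino acid; stops one family."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    groups: dict[str, list[str]] = {}
    for codon in ALL_CODONS_DNA:
        aa = "*" if codon in tab.stop_codons else tab.forward_table[codon]
        groups.setdefault(aa, []).append(to_rna(codon))
    return {aa: tuple(cs) for aa, cs in groups.items()}


FAMILY_MODES = ("standard", "mito")
_FAMILIES = {"standard": _families_from_table(1), "mito": _families_from_table(2)}


def codon_families(mode: str = "standard") -> dict[str, tuple[str, ...]]:
    """Amino-acid → synonymous-codon-family map (RNA alphabet)."""
    if mode not in FAMILY_MODES:
        raise ValueError(f"family mode must be one of {FAMILY_MODES}, got {mode!r}")
    return _FAMILIES[mode]


# ---------------------------------------------------------------------------
# codon extraction
# ---------------------------------------------------------------------------

@dataclass
class PcgCodonRecord:
    """Codon readout of one protein-coding gene on its sense strand."""

    gene: str
    start_codon: str
    stop_codon: Optional[str]   # complete 3-mer, "TA-", "T--", or None if untypable
    codons: list[str]           # complete triplets incl. a complete terminal stop
    warnings: list[str] = field(default_factory=list)

    @property
    def stop_remainder(self) -> int:
        """Trailing bases not forming a full codon (0, 1 or 2)."""
        if self.stop_codon == "TA-":
            return 2
        if self.stop_codon == "T--":
            return 1
        return 0

    @property
    def length(self) -> int:
        return 3 * len(self.codons) + self.stop_remainder


def extract_codons(genome: CircularGenome, feature: GeneFeature) -> PcgCodonRecord:
    """Split a PCG's sense-strand sequence into codons and type its stop.

    Length remainder 1 with a trailing T → ``T--``; remainder 2 with
    trailing TA → ``TA-``; any other remainder content is flagged as
    annotation-inconsistent (stop_codon None).  A complete terminal triplet
    is recognized as the stop only if it is a transl_table=2 stop.
    Internal stop codons are recorded as warnings, not errors, so
    provisional annotations can still be analysed.
    """
    if feature.feature_class != PCG:
        raise FeatureValidationError(
            f"{feature.name}: extract_codons needs a PCG, got {feature.feature_class}"
        )
    seq = feature.sense_sequence(genome)
    warnings: list[str] = []
    remainder = len(seq) % 3
    stop: Optional[str]
    if remainder == 1:
        if seq[-1] == "T":
            stop = "T--"
        else:
            stop = None
            warnings.append(
                f"length remainder 1 but trailing base {seq[-1]!r} != T; "
                "annotation-inconsistent stop"
            )
        body = seq[:-1]
    elif remainder == 2:
        if seq[-2:] == "TA":
            stop = "TA-"
        else:
            stop = None
            warnings.append(
                f"length remainder 2 but trailing bases {seq[-2:]!r} != TA; "
                "annotation-inconsistent stop"
            )
        body = seq[:-2]
    else:
        body = seq
        stop = seq[-3:] if seq[-3:] in MITO_STOPS else None
        if stop is None:
            warnings.append(
                f"terminal triplet {seq[-3:]!r} is not a vertebrate-mito stop codon"
            )
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    for idx, c in enumerate(codons[1:-1], start=2):
        if c in MITO_STOPS:
            warnings.append(f"internal stop codon {c} at codon position {idx}")
    for w in warnings:
        logger.warning("%s: %s", feature.name, w)
    return PcgCodonRecord(gene=feature.name, start_codon=codons[0],
                          stop_codon=stop, codons=codons, warnings=warnings)


# ---------------------------------------------------------------------------
# counting and RSCU
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """64-codon counts plus RSCU values under a synonymous-family partition."""

    counts: dict[str, int]                      # RNA-alphabet keys, all 64 present
    family_mode: str = "standard"
    rscu: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self):
        full = {to_rna(c): 0 for c in ALL_CODONS_DNA}
        full.update({to_rna(k): int(v) for k, v in self.counts.items()})
        if any(v < 0 for v in full.values()):
            raise FeatureValidationError("codon counts must be >= 0")
        self.counts = full

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        return codon_families(self.family_mode)

    def family_of(self, codon: str) -> tuple[str, tuple[str, ...]]:
        codon = to_rna(codon)
        for aa, fam in self.families.items():
            if codon in fam:
                return aa, fam
        raise KeyError(codon)

    def to_frame(self, precision: int = 2) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for aa, fam in sorted(self.families.items()):
            for c in fam:
                v = self.rscu.get(c)
                rows.append({
                    "codon": c, "aa": aa, "count": self.counts[c],
                    "RSCU": "" if v is None else _round_half_up(v, precision),
                })
        return pd.DataFrame(rows)


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def count_codons(records: Iterable[PcgCodonRecord],
                 include_stops: bool = True,
                 family_mode: str = "standard") -> CodonUsageTable:
    """Aggregate codon counts across PCGs.

    Incomplete stops contribute nothing.  With ``include_stops=False`` a
    complete terminal stop triplet is excluded from the tally.  Codons
    containing N are skipped and logged.
    """
    records = list(records)
    if not records:
        raise FeatureValidationError("need at least one codon record")
    counts: dict[str, int] = {}
    skipped = 0
    for rec in records:
        codons = rec.codons
        if (not include_stops and rec.stop_codon in MITO_STOPS
                and codons and codons[-1] == rec.stop_codon):
            codons = codons[:-1]
        for c in codons:
            if "N" in c:
                skipped += 1
                continue
            key = to_rna(c)
            counts[key] = counts.get(key, 0) + 1
    if skipped:
        logger.warning("skipped %d codons containing N", skipped)
    return CodonUsageTable(counts=counts, family_mode=family_mode)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill the RSCU column: count × |family| / family total.

    Families with zero total get RSCU None (reported blank).
    """
    out: dict[str, Optional[float]] = {}
    for aa, fam in table.families.items():
        total = sum(table.counts[c] for c in fam)
        for c in fam:
            out[c] = None if total == 0 else table.counts[c] * len(fam) / total
    table.rscu = out
    return table


def rscu_from_counts(counts: dict[str, int],
                     family_mode: str = "standard") -> CodonUsageTable:
    """Convenience: build a table from raw counts and compute RSCU."""
    return rscu(CodonUsageTable(counts=counts, family_mode=family_mode))
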