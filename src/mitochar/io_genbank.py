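"""Reading/writing annotated mitogenomes and canonical gene-name resolution.

The pipeline works on two domain objects: :class:`CircularGenome` (sequence
plus declared length and topology) and :class:`GeneFeature` (one annotated
gene with 1-based inclusive coordinates, H/L strand, and an anticodon for
tRNAs).  Input records use wildly heterogeneous gene names (``ND5`` /
``NAD5`` / ``NADH dehydrogenase subunit 5``); everything is normalized into
a canonical 37-gene vertebrate vocabulary (13 PCGs, 22 tRNAs with the
L1/L2 and S1/S2 isoacceptor split, 2 rRNAs, control region) on the way in.

Coordinates are 1-based inclusive throughout the package; conversion to
0-based half-open happens only at I/O edges.  Features spanning the circular
origin are split into two sub-spans sharing a gene id (``part`` 1 and 2).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateGeneError,
    FeatureValidationError,
    GenBankParseError,
    SequenceAbsentError,
)

logger = logging.getLogger(__name__)

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"
FEATURE_CLASSES = (PCG, TRNA, RRNA, CONTROL_REGION)

#: canonical PCG ids in the conventional vertebrate concatenation order
PCG_ORDER = (
    "nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
    "nad3", "nad4l", "nad4", "nad5", "cob", "nad6",
)

TRNA_IDS = (
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA",
    "trnN", "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR",
    "trnH", "trnS1", "trnL1", "trnT", "trnP", "trnE",
)

RRNA_IDS = ("rrnS", "rrnL")
CONTROL_REGION_ID = "d-loop"

#: the full 37-gene vertebrate set plus the control region
CANONICAL_IDS = PCG_ORDER + TRNA_IDS + RRNA_IDS + (CONTROL_REGION_ID,)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CircularGenome:
    """A (usually circular) mitochondrial genome.

    ``seq`` may be ``None`` (feature-table-only mode): the genome then
    carries only a declared length, and sequence-dependent operations
    raise :class:`~mitochar.errors.SequenceAbsentError`.
    """

    id: str
    length: int
    seq: Optional[str] = None
    circular: bool = True

    def __post_init__(self):
        if self.length <= 0:
            raise FeatureValidationError(f"genome length must be > 0, got {self.length}")
        if self.seq is not None:
            self.seq = self.seq.upper()
            if len(self.seq) != self.length:
                raise FeatureValidationError(
                    f"declared length {self.length} != sequence length {len(self.seq)}"
                )

    @property
    def has_sequence(self) -> bool:
        return self.seq is not None

    def require_sequence(self, what: str = "operation") -> str:
        if self.seq is None:
            raise SequenceAbsentError(what)
        return self.seq

    def slice(self, start: int, end: int) -> str:
        """Extract the H-strand sequence of a 1-based inclusive span.

        ``start > end`` denotes a span wrapping through the circular origin.
        """
        seq = self.require_sequence("sequence slice")
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise FeatureValidationError(
                f"span {start}-{end} outside genome [1, {self.length}]"
            )
        if start <= end:
            return seq[start - 1:end]
        if not self.circular:
            raise FeatureValidationError(
                f"wrapping span {start}-{end} on a non-circular genome"
            )
        return seq[start - 1:] + seq[:end]


@dataclass
class GeneFeature:
    """One annotated gene: canonical name, class, strand and 1-based span."""

    name: str
    feature_class: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    mapped: bool = True          # False when the raw name had no canonical alias
    part: Optional[int] = None   # 1/2 for origin-split sub-spans

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise FeatureValidationError(
                f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}"
            )
        if self.start < 1 or self.end < self.start:
            raise FeatureValidationError(
                f"{self.name}: invalid span {self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.anticodon is not None:
            self.anticodon = self.anticodon.upper().replace("U", "T")
            if not re.fullmatch(r"[ACGTN]{3}", self.anticodon):
                raise FeatureValidationError(
                    f"{self.name}: anticodon must be a 3-mer, got {self.anticodon!r}"
                )
            if self.feature_class != TRNA:
                raise FeatureValidationError(
                    f"{self.name}: anticodon given but feature_class is "
                    f"{self.feature_class}, not tRNA"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sense_sequence(self, genome: CircularGenome) -> str:
        """Coding-strand (sense) sequence of this feature."""
        s = genome.slice(self.start, self.end)
        return revcomp(s) if self.strand == "L" else s


def sort_features(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    """Deterministic sort by start, tie-break by end, then name."""
    return sorted(features, key=lambda f: (f.start, f.end, f.name))


# ---------------------------------------------------------------------------
# gene-name normalization
# ---------------------------------------------------------------------------

_AA3 = {
    "phe": "F", "val": "V", "ile": "I", "gln": "Q", "met": "M", "trp": "W",
    "ala": "A", "asn": "N", "cys": "C", "tyr": "Y", "asp": "D", "lys": "K",
    "gly": "G", "arg": "R", "his": "H", "thr": "T", "pro": "P", "glu": "E",
}


def _alias_table() -> dict[str, set[str]]:
    t: dict[str, set[str]] = {}

    def add(canon, *aliases):
        t.setdefault(canon, set()).update(a.lower() for a in aliases)
        t[canon].add(canon.lower())

    for i in (1, 2, 3, 4, 5, 6):
        add(f"nad{i}", f"nd{i}", f"nadh{i}", f"nadh dehydrogenase subunit {i}",
            f"mt-nd{i}", f"nadh-{i}")
    add("nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l", "mt-nd4l")
    roman = {1: "i", 2: "ii", 3: "iii"}
    for i in (1, 2, 3):
        add(f"cox{i}", f"co{i}", f"coxi{'i' * (i - 1)}", f"co{roman[i]}",
            f"cytochrome c oxidase subunit {i}",
            f"cytochrome c oxidase subunit {roman[i]}", f"mt-co{i}")
    add("atp6", "atpase6", "atpase 6", "atp synthase f0 subunit 6", "mt-atp6")
    add("atp8", "atpase8", "atpase 8", "atp synthase f0 subunit 8", "mt-atp8")
    add("cob", "cytb", "cyt b", "cytochrome b", "mt-cyb", "cyb")
    add("rrnS", "12s", "12s rrna", "12s ribosomal rna", "s-rrna", "srrna",
        "small subunit ribosomal rna", "mt-rnr1", "rrn12")
    add("rrnL", "16s", "16s rrna", "16s ribosomal rna", "l-rrna", "lrrna",
        "large subunit ribosomal rna", "mt-rnr2", "rrn16")
    add(CONTROL_REGION_ID, "oh", "d loop", "dloop", "control region", "cr",
        "putative control region", "mt-dloop")
    for aa3, aa1 in _AA3.items():
        add(f"trn{aa1}", f"trna-{aa3}", f"trna {aa3}", f"trn{aa1.lower()}")
    # isoacceptor splits: Leu(UUR)=trnL2, Leu(CUN)=trnL1, Ser(AGY)=trnS1, Ser(UCN)=trnS2
    add("trnL1", "trnl(cun)", "trna-leu(cun)", "trnl-tag", "trna-leu (cun)")
    add("trnL2", "trnl(uur)", "trna-leu(uur)", "trnl-taa", "trna-leu (uur)")
    add("trnS1", "trns(agy)", "trna-ser(agy)", "trns-gct", "trna-ser (agy)")
    add("trnS2", "trns(ucn)", "trna-ser(ucn)", "trns-tga", "trna-ser (ucn)")
    return t


#: canonical id -> set of lower-cased aliases (pairwise disjoint)
GENE_NAME_MAP: dict[str, set[str]] = _alias_table()

_ALIAS_LOOKUP: dict[str, str] = {}
for _canon, _aliases in GENE_NAME_MAP.items():
    for _a in _aliases:
        _ALIAS_LOOKUP[_a] = _canon
        _ALIAS_LOOKUP[_a.replace(" ", "")] = _canon


def normalize_gene_name(raw: str) -> str:
    """Resolve a raw gene name to its canonical id.

    Case-insensitive; whitespace/underscores are insignificant.  Unknown
    names are returned unchanged (tagged by :func:`is_canonical` being
    False downstream), never dropped.
    """
    key = raw.strip().lower().replace("_", " ")
    for k in (key, key.replace(" ", "")):
        if k in _ALIAS_LOOKUP:
            return _ALIAS_LOOKUP[k]
    return raw.strip()


def is_canonical(name: str) -> bool:
    return name in CANONICAL_IDS


def default_class(name: str) -> Optional[str]:
    """Infer feature class from a canonical id, or None if unknown."""
    if name in PCG_ORDER:
        return PCG
    if name in TRNA_IDS:
        return TRNA
    if name in RRNA_IDS:
        return RRNA
    if name == CONTROL_REGION_ID:
        return CONTROL_REGION
    return None


def _check_duplicates(features: list[GeneFeature]) -> None:
    seen: dict[str, GeneFeature] = {}
    for f in features:
        if not f.mapped or f.part not in (None, 1):
            continue
        if f.name in seen:
            prev = seen[f.name]
            raise DuplicateGeneError(f.name, (prev.start, prev.end), (f.start, f.end))
        seen[f.name] = f


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_GB_TYPE_TO_CLASS = {
    "CDS": PCG,
    "tRNA": TRNA,
    "rRNA": RRNA,
    "D-loop": CONTROL_REGION,
}
_CLASS_TO_GB_TYPE = {v: k for k, v in _GB_TYPE_TO_CLASS.items()}

_ANTICODON_RE = re.compile(r"seq\s*:\s*([acgtun]{3})", re.IGNORECASE)


def _feature_name(feat) -> Optional[str]:
    q = feat.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            return q[key][0]
    if feat.type == "D-loop":
        return "D-loop"
    return None


def _feature_anticodon(feat) -> Optional[str]:
    q = feat.qualifiers
    if "anticodon" in q and q["anticodon"]:
        raw = q["anticodon"][0]
        if re.fullmatch(r"[ACGTUacgtu]{3}", raw):
            return raw
        m = _ANTICODON_RE.search(raw)
        if m:
            return m.group(1)
    return None


def _locations_to_spans(feat, genome_length: int) -> list[tuple[int, int]]:
    """1-based inclusive spans; origin-spanning compound locations split."""
    loc = feat.location
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    return [(int(p.start) + 1, int(p.end)) for p in parts]


def read_genbank(path) -> tuple[CircularGenome, list[GeneFeature]]:
    """Read a GenBank flat file into a genome plus normalized feature list.

    Feature names are mapped through the canonical alias table; unmappable
    features are retained with the record's feature class and flagged with
    ``mapped=False`` (a warning is logged).  Features are returned sorted
    by start (tie-break end, then name).
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise GenBankParseError(f"{path}: malformed GenBank record: {exc}") from exc

    length = len(record.seq)
    try:
        seq = str(record.seq)
        if set(seq) == set():
            seq = None
    except Exception:  # undefined sequence (CONTIG-only record)
        seq = None
    circular = record.annotations.get("topology", "circular") == "circular"
    genome = CircularGenome(id=record.id or record.name, length=length,
                            seq=seq, circular=circular)

    feats: list[GeneFeature] = []
    covered_genes: set[tuple[str, int]] = set()
    # typed features first; bare 'gene' features only as fallback
    for typed in (True, False):
        for feat in record.features:
            if typed and feat.type not in _GB_TYPE_TO_CLASS:
                continue
            if not typed and feat.type != "gene":
                continue
            raw = _feature_name(feat)
            if raw is None:
                continue
            name = normalize_gene_name(raw)
            mapped = is_canonical(name)
            spans = _locations_to_spans(feat, length)
            if not typed and (name, spans[0][0]) in covered_genes:
                continue
            fclass = _GB_TYPE_TO_CLASS.get(feat.type) or default_class(name) or PCG
            if not mapped:
                logger.warning("unmappable gene name %r kept as-is (class %s)",
                               raw, fclass)
            strand = "L" if (feat.location.strand or 1) < 0 else "H"
            anticodon = _feature_anticodon(feat) if fclass == TRNA else None
            for i, (s, e) in enumerate(spans):
                feats.append(GeneFeature(
                    name=name, feature_class=fclass, strand=strand,
                    start=s, end=e, anticodon=anticodon, mapped=mapped,
                    part=(i + 1) if len(spans) > 1 else None,
                ))
                covered_genes.add((name, s))

    feats = sort_features(feats)
    _check_duplicates(feats)
    return genome, feats


def write_genbank(genome: CircularGenome, features: list[GeneFeature], path) -> None:
    """Write a genome + features as a GenBank flat file (sequence required)."""
    seq = genome.require_sequence("GenBank output")
    record = SeqRecord(Seq(seq), id=genome.id, name=genome.id[:16].replace(".", ""),
                       description="mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    by_id: dict[tuple, list[GeneFeature]] = {}
    for f in features:
        by_id.setdefault((f.name, f.part is not None), []).append(f)
    for (name, split), group in by_id.items():
        group = sort_features(group)
        strand = 1 if group[0].strand == "H" else -1
        locs = [FeatureLocation(f.start - 1, f.end, strand=strand) for f in group]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [name]}
        if group[0].anticodon:
            qualifiers["anticodon"] = [group[0].anticodon.lower()]
        record.features.append(
            SeqFeature(loc, type=_CLASS_TO_GB_TYPE[group[0].feature_class],
                       qualifiers=qualifiers)
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + feature-table I/O
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = True) -> CircularGenome:
    record = SeqIO.read(str(path), "fasta")
    return CircularGenome(id=record.id, length=len(record.seq),
                          seq=str(record.seq), circular=circular)


def write_fasta(genome: CircularGenome, path) -> None:
    seq = genome.require_sequence("FASTA output")
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


FEATURE_TABLE_COLUMNS = ("name", "class", "strand", "start", "end", "anticodon")


def read_feature_table(path, genome_length: int) -> list[GeneFeature]:
    """Read a TSV feature table (columns: name, [class], strand, start, end,
    [anticodon]); missing class is inferred from the canonical name.

    This lets a published annotation table be typed in directly and analysed
    with no sequence download (feature-table-only mode).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "strand", "start", "end"}
    if not required <= set(df.columns):
        raise GenBankParseError(
            f"{path}: feature table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    feats = []
    for idx, row in df.iterrows():
        name = normalize_gene_name(str(row["name"]))
        mapped = is_canonical(name)
        strand = str(row["strand"]).strip()
        if strand in ("+", "1"):
            strand = "H"
        elif strand in ("-", "-1"):
            strand = "L"
        if strand not in ("H", "L"):
            raise FeatureValidationError(
                f"{path} row {idx + 2}: strand must be H or L, got {strand!r}"
            )
        start, end = int(row["start"]), int(row["end"])
        if start > end:
            raise FeatureValidationError(
                f"{path} row {idx + 2} ({name}): start {start} > end {end}"
            )
        if end > genome_length:
            raise FeatureValidationError(
                f"{path} row {idx + 2} ({name}): end {end} > genome length "
                f"{genome_length}"
            )
        fclass = None
        if "class" in df.columns and isinstance(row.get("class"), str) and row["class"].strip():
            fclass = row["class"].strip()
            if fclass not in FEATURE_CLASSES:
                raise FeatureValidationError(
                    f"{path} row {idx + 2}: unknown feature class {fclass!r}"
                )
        fclass = fclass or default_class(name)
        if fclass is None:
            logger.warning("row %d: cannot infer class of %r, assuming PCG", idx + 2, name)
            fclass = PCG
        anticodon = None
        if "anticodon" in df.columns and isinstance(row.get("anticodon"), str):
            a = row["anticodon"].strip()
            anticodon = a if a else None
        if fclass != TRNA:
            anticodon = None
        feats.append(GeneFeature(name=name, feature_class=fclass, strand=strand,
                                 start=start, end=end, anticodon=anticodon,
                                 mapped=mapped))
    feats = sort_features(feats)
    _check_duplicates(feats)
    return feats


def write_feature_table(features: list[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
        for f in features:
            fh.write(f"{f.name}\t{f.feature_class}\t{f.strand}\t{f.start}\t"
                     f"{f.end}\t{f.anticodon or ''}\n")
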