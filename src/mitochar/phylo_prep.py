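"""13-PCG supermatrix construction, MrBayes input emission, topology checks.

Alignment and Bayesian MCMC themselves are delegated to external tools
(MAFFT/MEGA, MrBayes); this module concatenates *pre-aligned* per-gene
blocks into a partitioned supermatrix, writes an inference-ready NEXUS
with a MrBayes block (defaults: GTR+G+I via nst=6 rates=invgamma, 4
chains, 400,000 generations, sampling every 100, 25% burn-in), and
asserts nested-clade constraints on a resulting tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import dendropy

from .errors import (
    AlignmentRequiredError,
    FeatureValidationError,
    TaxonLookupError,
)
from .io_genbank import PCG, PCG_ORDER, CircularGenome, GeneFeature

MISSING = "?"


@dataclass
class Supermatrix:
    """Concatenated per-gene alignment with 1-based partition spans."""

    taxa: list[str]
    partitions: list[tuple[str, int, int]]
    matrix: dict[str, str]
    missing_char: str = MISSING

    def __post_init__(self):
        widths = {len(s) for s in self.matrix.values()}
        if len(widths) > 1:
            raise FeatureValidationError(f"unequal row lengths: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0


def extract_pcg_sequences(genome: CircularGenome,
                          features: Iterable[GeneFeature]) -> dict[str, str]:
    """Sense-strand nucleotide sequence of each annotated PCG."""
    return {f.name: f.sense_sequence(genome)
            for f in features if f.feature_class == PCG}


def build_supermatrix(taxon_genes: dict[str, dict[str, str]],
                      gene_set: Sequence[str] = PCG_ORDER,
                      strip_missing: bool = False,
                      missing_char: str = MISSING) -> Supermatrix:
    """Concatenate per-gene blocks across taxa in canonical PCG order.

    Per-gene sequences must be equal-length across the taxa that have the
    gene (pre-aligned input) — otherwise an alignment-required error points
    the user to an external aligner.  A taxon lacking a gene is padded with
    ``missing_char`` over that partition; ``strip_missing`` afterwards drops
    every column containing the missing/gap symbol in any taxon.
    """
    taxa = list(taxon_genes)
    if not taxa:
        raise FeatureValidationError("no taxa given")
    for taxon, genes in taxon_genes.items():
        if not genes:
            raise FeatureValidationError(f"taxon {taxon!r} has zero genes")

    gene_lengths: dict[str, int] = {}
    for gene in gene_set:
        lengths = {t: len(g[gene]) for t, g in taxon_genes.items() if gene in g}
        if not lengths:
            continue
        if len(set(lengths.values())) > 1:
            raise AlignmentRequiredError(
                f"gene {gene!r} has unequal lengths across taxa "
                f"({dict(sorted(lengths.items()))}); align the per-gene "
                "sequences with an external aligner (e.g. MAFFT) first"
            )
        gene_lengths[gene] = next(iter(lengths.values()))

    partitions = []
    col = 1
    rows = {t: [] for t in taxa}
    for gene, L in gene_lengths.items():
        partitions.append((gene, col, col + L - 1))
        col += L
        for t in taxa:
            rows[t].append(taxon_genes[t].get(gene, missing_char * L).upper())
    matrix = {t: "".join(parts) for t, parts in rows.items()}
    sm = Supermatrix(taxa=taxa, partitions=partitions, matrix=matrix,
                     missing_char=missing_char)
    return strip_missing_columns(sm) if strip_missing else sm


def strip_missing_columns(sm: Supermatrix) -> Supermatrix:
    """Drop every column holding the missing char or a gap in any taxon,
    re-spanning the partitions accordingly."""
    bad = set()
    drop_chars = {sm.missing_char, "-"}
    for seq in sm.matrix.values():
        for i, ch in enumerate(seq):
            if ch in drop_chars:
                bad.add(i)
    keep = [i for i in range(sm.width) if i not in bad]
    new_matrix = {t: "".join(s[i] for i in keep) for t, s in sm.matrix.items()}
    # re-span partitions over surviving columns
    new_partitions = []
    col = 1
    for gene, s, e in sm.partitions:
        kept = sum(1 for i in keep if s - 1 <= i <= e - 1)
        if kept:
            new_partitions.append((gene, col, col + kept - 1))
            col += kept
    return Supermatrix(taxa=sm.taxa, partitions=new_partitions,
                       matrix=new_matrix, missing_char=sm.missing_char)


# ---------------------------------------------------------------------------
# NEXUS emission / ingestion
# ---------------------------------------------------------------------------

@dataclass
class MrBayesSettings:
    """Run settings encoded in the emitted mrbayes block."""

    nst: int = 6
    rates: str = "invgamma"      # nst=6 + invgamma == GTR+G+I
    nchains: int = 4
    ngen: int = 400_000
    samplefreq: int = 100
    burninfrac: float = 0.25


def write_mrbayes_nexus(sm: Supermatrix, path,
                        settings: Optional[MrBayesSettings] = None) -> None:
    """Write a MrBayes-dialect NEXUS: data matrix, charsets, mrbayes block."""
    if not sm.taxa:
        raise FeatureValidationError("cannot write a 0-taxon matrix")
    settings = settings or MrBayesSettings()
    name_w = max(len(t) for t in sm.taxa) + 2
    lines = [
        "#NEXUS", "",
        "begin data;",
        f"  dimensions ntax={len(sm.taxa)} nchar={sm.width};",
        f"  format datatype=dna missing={sm.missing_char} gap=-;",
        "  matrix",
    ]
    for t in sm.taxa:
        label = t.replace(" ", "_")
        lines.append(f"    {label:<{name_w}}{sm.matrix[t]}")
    lines += ["  ;", "end;", "", "begin mrbayes;"]
    for gene, s, e in sm.partitions:
        lines.append(f"  charset {gene} = {s}-{e};")
    if sm.partitions:
        names = ", ".join(g for g, _, _ in sm.partitions)
        lines.append(f"  partition genes = {len(sm.partitions)}: {names};")
        lines.append("  set partition = genes;")
    lines += [
        f"  lset applyto=(all) nst={settings.nst} rates={settings.rates};",
        f"  mcmc nchains={settings.nchains} ngen={settings.ngen} "
        f"samplefreq={settings.samplefreq};",
        f"  sumt burninfrac={settings.burninfrac};",
        "end;",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_nexus(path) -> Supermatrix:
    """Read back a NEXUS written by :func:`write_mrbayes_nexus`."""
    taxa, matrix, partitions = [], {}, []
    missing = MISSING
    in_matrix = False
    for raw in open(path):
        line = raw.strip()
        low = line.lower()
        if low.startswith("format"):
            for tok in line.rstrip(";").split():
                if tok.lower().startswith("missing="):
                    missing = tok.split("=", 1)[1]
        elif low.startswith("matrix"):
            in_matrix = True
        elif in_matrix:
            if line == ";":
                in_matrix = False
                continue
            label, seq = line.split(None, 1)
            taxa.append(label)
            matrix[label] = seq.strip()
        elif low.startswith("charset"):
            _, rest = line.split(None, 1)
            gene, span = rest.rstrip(";").split("=")
            s, e = span.strip().split("-")
            partitions.append((gene.strip(), int(s), int(e)))
    return Supermatrix(taxa=taxa, partitions=partitions, matrix=matrix,
                       missing_char=missing)


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP output."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.width}\n")
        for t in sm.taxa:
            fh.write(f"{t.replace(' ', '_')}  {sm.matrix[t]}\n")


# ---------------------------------------------------------------------------
# topology assertions
# ---------------------------------------------------------------------------

#: nested-group expression: a leaf/genus name, or a sequence of sub-groups
GroupExpr = Union[str, Sequence]


def parse_group_expression(text: str) -> list:
    """Parse a nested-group string like
    ``((((Monticola + Saxicola) + Oenanthe) + Phoenicurus) + Myophonus)``
    into nested lists of names."""
    text = text.strip()
    pos = 0

    def parse():
        nonlocal pos
        while pos < len(text) and text[pos] in " +":
            pos += 1
        if text[pos] == "(":
            pos += 1
            items = []
            while True:
                items.append(parse())
                while pos < len(text) and text[pos] in " +":
                    pos += 1
                if text[pos] == ")":
                    pos += 1
                    return items
        start = pos
        while pos < len(text) and text[pos] not in "()+":
            pos += 1
        return text[start:pos].strip()

    return parse()


def read_tree(source: str) -> dendropy.Tree:
    """Read a newick tree from a string or file path."""
    import os

    if os.path.exists(str(source)):
        return dendropy.Tree.get(path=str(source), schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")


def _expand(name: str, leaves: list[str]) -> set[str]:
    """Map a constraint name to matching leaf labels (genus prefix match)."""
    exact = {l for l in leaves if l == name}
    if exact:
        return exact
    pref = {l for l in leaves if l.split()[0] == name or l.split("_")[0] == name
            or l.startswith(name)}
    if not pref:
        raise TaxonLookupError(f"constraint taxon {name!r} matches no leaf")
    return pref


def _collect_groups(expr: GroupExpr, leaves: list[str],
                    out: list[set[str]]) -> set[str]:
    if isinstance(expr, str):
        return _expand(expr, leaves)
    members: set[str] = set()
    for sub in expr:
        members |= _collect_groups(sub, leaves, out)
    out.append(members)
    return members


def assert_topology(tree: Union[dendropy.Tree, str],
                    constraint: GroupExpr) -> tuple[bool, Optional[set[str]]]:
    """True iff every nested group in the constraint is a clade of the tree.

    The tree is taken as rooted (outgroup-rooted); a group is a clade when
    the MRCA of its leaves subtends exactly those leaves.  Returns
    ``(ok, witness)`` where witness is the first violated group's leaf set.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    if isinstance(constraint, str) and ("(" in constraint or "+" in constraint):
        constraint = parse_group_expression(constraint)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise FeatureValidationError("duplicate leaf labels in tree")
    groups: list[set[str]] = []
    _collect_groups(constraint, leaves, groups)
    clades = _clade_sets(tree)
    for g in groups:
        if len(g) >= 2 and frozenset(g) not in clades:
            return False, g
    return True, None


def _clade_sets(tree: dendropy.Tree) -> set[frozenset]:
    out = set()
    for node in tree.preorder_node_iter():
        out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out
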