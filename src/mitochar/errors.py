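"""Exception hierarchy for mitochar."""


class MitocharError(Exception):
    """Base class for all mitochar errors."""


class GenBankParseError(MitocharError):
    """A GenBank/FASTA/TSV input could not be parsed."""


class FeatureValidationError(MitocharError):
    """An annotated feature violates the coordinate/strand contract."""


class DuplicateGeneError(FeatureValidationError):
    """Two features resolve to the same canonical gene id."""

    def __init__(self, name, span_a, span_b):
        self.name = name
        self.spans = (span_a, span_b)
        super().__init__(
            f"duplicate canonical gene id {name!r}: spans {span_a} and {span_b}"
        )


class SequenceAbsentError(MitocharError):
    """A sequence-dependent operation was invoked in feature-table-only mode."""

    def __init__(self, what="operation"):
        super().__init__(
            f"{what} requires the nucleotide sequence, but the genome is in "
            "feature-table-only mode (declared length, no sequence)"
        )


class UndefinedSkewError(MitocharError):
    """Skew denominator is zero (A+T == 0 or G+C == 0)."""


class RegionLookupError(MitocharError):
    """A requested region name matches no annotated feature."""


class NoCloverleafError(MitocharError):
    """No cloverleaf template placement reaches the minimum pairing."""


class AlignmentRequiredError(MitocharError):
    """Per-gene sequences differ in length across taxa; align them first."""


class TaxonLookupError(MitocharError):
    """A topology constraint names a taxon absent from the tree."""


class SpecValidationError(MitocharError):
    """A synthetic-genome spec is internally inconsistent."""
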