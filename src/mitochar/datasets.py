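"""Bundled reference tables for the Myophonus caeruleus mitogenome.

The package ships the published annotation (gene spans, strands,
anticodons), per-codon counts over the 13 protein-coding genes, and
per-region base composition of GenBank accession MN564936 as small TSV
files, so all feature-table-only analytics run with zero downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_genbank import GeneFeature, read_feature_table

#: declared length (bp) of the MN564936 mitogenome
MN564936_LENGTH = 16815

#: published start/stop codon typing of the 13 PCGs ("TA-"/"T--" are
#: incomplete stops completed by polyadenylation)
MN564936_START_CODONS = {
    "nad1": "ATG", "nad2": "ATG", "cox1": "GTG", "cox2": "ATG",
    "atp8": "ATG", "atp6": "ATG", "cox3": "ATG", "nad3": "ATG",
    "nad4l": "ATG", "nad4": "ATG", "nad5": "ATG", "cob": "ATG",
    "nad6": "ATG",
}
MN564936_STOP_CODONS = {
    "nad1": "TA-", "nad2": "TAA", "cox1": "AGG", "cox2": "TAA",
    "atp8": "TAA", "atp6": "TAA", "cox3": "T--", "nad3": "TAA",
    "nad4l": "TAA", "nad4": "T--", "nad5": "AGA", "cob": "TAA",
    "nad6": "TAG",
}


def _data_path(name: str):
    return resources.files("mitochar.data").joinpath(name)


def reference_features() -> list[GeneFeature]:
    """The 37 annotated genes + control region of MN564936 (sorted by start)."""
    with resources.as_file(_data_path("mn564936_features.tsv")) as p:
        return read_feature_table(p, MN564936_LENGTH)


def reference_codon_counts() -> dict[str, int]:
    """Published 64-codon counts (RNA-alphabet keys) over the 13 PCGs."""
    with resources.as_file(_data_path("mn564936_codon_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["codon"], df["count"].astype(int)))


def reference_composition() -> pd.DataFrame:
    """Published per-region base percentages (A/C/G/T) of MN564936."""
    with resources.as_file(_data_path("mn564936_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
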