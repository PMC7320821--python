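"""Readers and writers for the tabular and sequence formats the pipeline uses.

Expression and metabolite matrices travel as tab-separated tables (row ids in
the first column, one header row, ``.`` decimal, no quoting); sequences as
plain multi-FASTA.  All read/write pairs round-trip exactly up to float
formatting at 12 significant digits.

Also hosts :func:`translate_longest`, the conservative six-frame translation
rule used to turn candidate transcripts into protein sequences: the frame is
chosen that yields the longest methionine-initiated open reading frame.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "MetaboliteMatrix",
    "read_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_metabolite_matrix",
    "write_metabolite_matrix",
    "read_annotation",
    "write_annotation",
    "translate_longest",
]

_FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates the expected layout or invariants."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SeqRecord]:
    """Read a multi-FASTA file; ids must be unique and the file non-empty."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate sequence ids {dupes}")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records as FASTA with 60-column line wrapping."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Matrices and tables


def read_matrix_tsv(path, *, require_non_negative: bool = True) -> pd.DataFrame:
    """Read a numeric matrix TSV (row ids in first column, tissue header).

    Rejects ragged rows, non-numeric cells, duplicate row ids and — by
    default — negative values, naming the offending row and column.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate row ids {dupes}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate column ids")
    try:
        values = df.astype(float)
    except ValueError:
        for row in df.index:
            for col in df.columns:
                try:
                    float(df.at[row, col])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                    ) from None
        raise
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError(f"{path}: non-finite values present")
    if require_non_negative and (values.to_numpy() < 0).any():
        loc = np.argwhere(values.to_numpy() < 0)[0]
        raise FormatError(
            f"{path}: negative value at row {values.index[loc[0]]!r}, "
            f"column {values.columns[loc[1]]!r}"
        )
    values.index.name = df.index.name or "id"
    return values


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a matrix TSV bit-reproducibly (12 significant digits)."""
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=matrix.index.name or "id")


@dataclasses.dataclass
class MetaboliteMatrix:
    """Mass-feature intensities across tissues plus per-feature metadata.

    ``intensities`` is features x tissues; ``metadata`` is indexed by the same
    feature ids with columns ``neutral_mass`` (Da, monoisotopic), ``compound_class``
    and optional ``name``.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.metadata.index):
            raise FormatError("metabolite metadata index does not match intensity rows")
        masses = self.metadata["neutral_mass"].dropna()
        if (masses <= 0).any():
            raise FormatError("metabolite neutral masses must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def features_of_class(self, compound_class: str) -> list[str]:
        mask = self.metadata["compound_class"] == compound_class
        return list(self.metadata.index[mask])


def read_metabolite_matrix(matrix_path, metadata_path) -> MetaboliteMatrix:
    intensities = read_matrix_tsv(matrix_path)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    required = {"neutral_mass", "compound_class"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{metadata_path}: missing metadata columns {sorted(missing)}")
    meta = meta.reindex(intensities.index)
    if meta["neutral_mass"].isna().any():
        absent = list(meta.index[meta["neutral_mass"].isna()])[:5]
        raise FormatError(f"{metadata_path}: metadata missing for features {absent}")
    return MetaboliteMatrix(intensities=intensities, metadata=meta)


def write_metabolite_matrix(mm: MetaboliteMatrix, matrix_path, metadata_path) -> None:
    write_matrix_tsv(mm.intensities, matrix_path)
    mm.metadata.to_csv(metadata_path, sep="\t", float_format=_FLOAT_FMT, index_label="feature_id")


# ---------------------------------------------------------------------------
# Annotation


def read_annotation(path) -> pd.DataFrame:
    """Read a transcript annotation table.

    Columns: ``transcript_id``, ``length_bp`` (positive integer),
    ``enzyme_class`` (semicolon-separated labels, possibly empty) and
    ``is_cyp`` (0/1).  Returns a DataFrame indexed by transcript id with
    ``enzyme_class`` parsed into tuples of labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["transcript_id", "length_bp", "enzyme_class", "is_cyp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    if df["transcript_id"].duplicated().any():
        dupes = sorted(df.loc[df["transcript_id"].duplicated(), "transcript_id"].unique())
        raise FormatError(f"{path}: duplicate transcript ids {dupes}")
    try:
        lengths = df["length_bp"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer length_bp ({exc})") from exc
    if (lengths < 1).any():
        raise FormatError(f"{path}: length_bp must be >= 1")
    classes = [
        tuple(lbl for lbl in str(cell).split(";") if lbl) if pd.notna(cell) else ()
        for cell in df["enzyme_class"]
    ]
    out = pd.DataFrame(
        {
            "length_bp": lengths.to_numpy(),
            "enzyme_class": classes,
            "is_cyp": df["is_cyp"].astype(int).astype(bool).to_numpy(),
        },
        index=pd.Index(df["transcript_id"], name="transcript_id"),
    )
    return out


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "transcript_id": annotation.index,
            "length_bp": annotation["length_bp"].astype(int).to_numpy(),
            "enzyme_class": [";".join(c) for c in annotation["enzyme_class"]],
            "is_cyp": annotation["is_cyp"].astype(int).to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Translation-frame selection

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def translate_longest(sequence: str) -> str:
    """Translate the longest Met-initiated ORF found in any of the six frames.

    The ORF starts at an exact ``ATG``, extends codon by codon and stops at
    the first true stop codon (TAA/TAG/TGA) or the end of the frame.  Codons
    containing ``N`` translate to ``X`` and do not terminate the ORF.  Ties
    between equally long ORFs are broken deterministically: forward strand
    before reverse, lower frame offset, leftmost start.  Returns the empty
    string when no frame contains an ``ATG``.
    """
    seq = sequence.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    best = ""
    for strand_seq in (seq, seq.translate(_COMPLEMENT)[::-1]):
        for offset in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(offset, len(strand_seq) - 2, 3)
            ]
            stop_after = len(codons)
            # walk codons; restart the "current ORF" bookkeeping lazily
            starts = [i for i, c in enumerate(codons) if c == "ATG"]
            stops = [i for i, c in enumerate(codons) if c in _STOPS]
            for start in starts:
                end = next((s for s in stops if s >= start), stop_after)
                length = end - start
                if length > len(best):
                    best = "".join(_translate_codon(c) for c in codons[start:end])
    return best
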