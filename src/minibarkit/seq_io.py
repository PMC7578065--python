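"""Reading, validating, trimming and slicing taxonomy-labelled alignments.

The central object is :class:`AlignedSeqSet`: a multiple sequence alignment
of homologous marker sequences (e.g. a 12S rRNA fragment) in which every
record carries a four-rank taxonomy (order / family / genus / species).
Taxonomy comes either from structured FASTA headers
(``>id|order|family|genus|species`` by default) or from a sidecar TSV with
columns ``id, order, family, genus, species``; the sidecar wins when both
are present.

All coordinates are 1-based and inclusive, matching the convention used for
annotating marker positions on reference mitogenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SeqRecord",
    "AlignedSeqSet",
    "RegionCoords",
    "AlignmentError",
    "TaxonomyError",
    "read_alignment",
    "write_alignment",
    "trim_ambiguous_ends",
    "extract_region",
]

#: IUPAC nucleotide one-letter codes plus the gap symbol.
VALID_SYMBOLS = frozenset("ACGTRYSWKMBDHVN-")

#: Symbols treated as "missing" when trimming ragged alignment ends.
MISSING_SYMBOLS = frozenset("N-")

HEADER_FIELDS = ("id", "order", "family", "genus", "species")


class AlignmentError(ValueError):
    """Malformed alignment: ragged rows, empty sets, bad symbols."""


class TaxonomyError(ValueError):
    """A record whose taxonomy cannot be resolved."""


@dataclass(frozen=True)
class SeqRecord:
    """One aligned specimen sequence with its taxonomy.

    ``residues`` is an upper-case string over the IUPAC nucleotide alphabet
    plus ``-`` for alignment gaps; ``U`` is mapped to ``T`` on construction
    via :func:`read_alignment`.
    """

    id: str
    species: str
    residues: str
    genus: str = ""
    family: str = ""
    order: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise TaxonomyError("record with empty id")
        if not self.species:
            raise TaxonomyError(f"record {self.id!r} has no species")
        if not self.residues:
            raise AlignmentError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - VALID_SYMBOLS
        if bad:
            raise AlignmentError(
                f"record {self.id!r} contains invalid symbols: {sorted(bad)}"
            )


@dataclass(frozen=True)
class RegionCoords:
    """1-based inclusive column range on an alignment or template."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AlignmentError(
                f"invalid region {self.start}..{self.end}: need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class AlignedSeqSet:
    """An immutable set of equal-length taxonomy-labelled sequences."""

    def __init__(self, records: Sequence[SeqRecord]):
        records = list(records)
        if not records:
            raise AlignmentError("empty alignment")
        length = len(records[0].residues)
        seen: set[str] = set()
        for i, rec in enumerate(records, start=1):
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"record {i} ({rec.id!r}) has length {len(rec.residues)}, "
                    f"expected {length}"
                )
            if rec.id in seen:
                raise AlignmentError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        self._records = tuple(records)
        self._length = length

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, i: int) -> SeqRecord:
        return self._records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, AlignedSeqSet) and self._records == other._records

    def __repr__(self) -> str:
        return f"AlignedSeqSet({len(self)} records x {self.length} columns)"

    # -- views ---------------------------------------------------------------
    @property
    def records(self) -> tuple[SeqRecord, ...]:
        return self._records

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return self._length

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self._records]

    def species_map(self) -> dict[str, str]:
        return {r.id: r.species for r in self._records}

    def column(self, col: int) -> str:
        """Return column ``col`` (1-based) as a string, one symbol per record."""
        if not 1 <= col <= self._length:
            raise AlignmentError(f"column {col} out of range 1..{self._length}")
        return "".join(r.residues[col - 1] for r in self._records)

    def taxonomy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "order": [r.order for r in self._records],
                "family": [r.family for r in self._records],
                "genus": [r.genus for r in self._records],
                "species": self.species,
            }
        )


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _parse_header(header: str, delimiter: str) -> dict[str, str]:
    parts = [p.strip() for p in header.split(delimiter)]
    if len(parts) >= 5:
        return dict(zip(HEADER_FIELDS, parts[:5]))
    if len(parts) == 2:
        # minimal dialect: id|species
        return {"id": parts[0], "species": parts[1]}
    return {"id": parts[0]}


def read_alignment(
    path: str | Path,
    taxonomy: str | Path | None = None,
    *,
    delimiter: str = "|",
) -> AlignedSeqSet:
    """Read an aligned FASTA with taxonomy from headers or a sidecar TSV.

    Parameters
    ----------
    path:
        Aligned FASTA. All records must have identical length.
    taxonomy:
        Optional TSV with columns ``id, order, family, genus, species``.
        When given it overrides any taxonomy parsed from headers.
    delimiter:
        Field separator inside FASTA headers
        (default ``|``: ``>id|order|family|genus|species``).

    Raises
    ------
    AlignmentError
        Ragged record lengths or duplicate ids (the offending record is named).
    TaxonomyError
        A record that cannot be resolved to a species.
    """
    path = Path(path)
    sidecar: dict[str, dict[str, str]] = {}
    if taxonomy is not None:
        table = pd.read_csv(taxonomy, sep="\t", dtype=str).fillna("")
        missing_cols = {"id", "species"} - set(table.columns)
        if missing_cols:
            raise TaxonomyError(f"taxonomy TSV lacks columns {sorted(missing_cols)}")
        for row in table.to_dict("records"):
            sidecar[row["id"]] = row

    records: list[SeqRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(bio.description, delimiter)
        rec_id = fields["id"]
        if rec_id in sidecar:
            fields = {**fields, **sidecar[rec_id]}
        if not fields.get("species"):
            raise TaxonomyError(f"no species for record {rec_id!r}")
        records.append(
            SeqRecord(
                id=rec_id,
                species=fields.get("species", ""),
                genus=fields.get("genus", ""),
                family=fields.get("family", ""),
                order=fields.get("order", ""),
                residues=_normalise(str(bio.seq)),
            )
        )
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return AlignedSeqSet(records)


def write_alignment(aln: AlignedSeqSet, path: str | Path, *, delimiter: str = "|") -> None:
    """Write the alignment as FASTA with ``id|order|family|genus|species`` headers."""
    bio_records = [
        _BioRecord(
            Seq(r.residues),
            id=delimiter.join([r.id, r.order, r.family, r.genus, r.species]),
            description="",
        )
        for r in aln
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def write_taxonomy(aln: AlignedSeqSet, path: str | Path) -> None:
    """Write the sidecar taxonomy TSV (columns id, order, family, genus, species)."""
    aln.taxonomy_frame().to_csv(path, sep="\t", index=False)


def _column_missing_frac(aln: AlignedSeqSet, col: int) -> float:
    column = aln.column(col)
    return sum(c in MISSING_SYMBOLS for c in column) / len(column)


def trim_ambiguous_ends(
    aln: AlignedSeqSet, max_missing_frac: float = 0.5
) -> tuple[AlignedSeqSet, RegionCoords]:
    """Drop leading/trailing columns dominated by gaps or ``N``.

    A terminal column is removed while its fraction of ``-``/``N`` symbols
    exceeds ``max_missing_frac``; interior columns are never touched. Returns
    the trimmed alignment together with the retained 1-based column range on
    the input frame. Idempotent.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    start, end = 1, aln.length
    while start <= end and _column_missing_frac(aln, start) > max_missing_frac:
        start += 1
    while end >= start and _column_missing_frac(aln, end) > max_missing_frac:
        end -= 1
    if start > end:
        raise AlignmentError("trimming removed every column")
    region = RegionCoords(start, end)
    if region.length == aln.length:
        return aln, region
    return extract_region(aln, region), region


def extract_region(aln: AlignedSeqSet, region: RegionCoords) -> AlignedSeqSet:
    """Column slice ``region.start..region.end`` (1-based inclusive)."""
    if region.end > aln.length:
        raise AlignmentError(
            f"region {region.start}..{region.end} exceeds alignment length {aln.length}"
        )
    return AlignedSeqSet(
        [replace(r, residues=r.residues[region.start - 1 : region.end]) for r in aln]
    )
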