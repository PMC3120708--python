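"""Readers and writers for the external file formats.

All coordinates in files are 1-based inclusive residue positions, matching
the DOMINO-style range convention (e.g. ``411-468``). TSV files are
tab-separated, UTF-8, with ``#``-prefixed comment lines ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Twenty standard residues plus 'X' (unknown), uppercase.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class ValidationError(ValueError):
    """A record is well-formed but violates a domain invariant."""


@dataclass(frozen=True)
class Protein:
    """A named amino-acid sequence; the coordinate frame for all ranges."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid protein id {self.id!r}")
        if not self.sequence:
            raise ValidationError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.id}: illegal residue(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _canonical(id_a: str, id_b: str) -> tuple[str, str]:
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass
class InteractionDB:
    """Deduplicated unordered protein-ID pairs with sequence lookup."""

    proteome: Mapping[str, Protein]
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        canon = {_canonical(a, b) for a, b in self.pairs}
        for a, b in canon:
            for pid in (a, b):
                if pid not in self.proteome:
                    raise ValidationError(f"pair id {pid!r} not in proteome")
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canonical(*pair) in self.pairs

    @property
    def self_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b in self.pairs if a == b}

    def add(self, id_a: str, id_b: str) -> None:
        for pid in (id_a, id_b):
            if pid not in self.proteome:
                raise ValidationError(f"pair id {pid!r} not in proteome")
        self.pairs.add(_canonical(id_a, id_b))

    def without(self, id_a: str, id_b: str) -> "InteractionDB":
        """Copy of the database with one unordered pair removed."""
        kept = self.pairs - {_canonical(id_a, id_b)}
        return InteractionDB(proteome=self.proteome, pairs=kept)

    def oriented_pairs(self) -> Iterator[tuple[Protein, Protein]]:
        """Yield both orientations of every unordered pair (one for self-pairs)."""
        for a, b in sorted(self.pairs):
            pa, pb = self.proteome[a], self.proteome[b]
            yield pa, pb
            if a != b:
                yield pb, pa


Interval = tuple[int, int]


def validate_interval(rng: Interval, length: int | None = None, what: str = "interval") -> None:
    start, end = rng
    if start < 1 or end < start:
        raise ValidationError(f"{what}: invalid range [{start},{end}]")
    if length is not None and end > length:
        raise ValidationError(
            f"{what}: range [{start},{end}] exceeds protein length {length}"
        )


@dataclass(frozen=True)
class LabSitePair:
    """Lab-confirmed binding-site ranges on both partners of an interaction."""

    id_a: str
    id_b: str
    range_a: Interval
    range_b: Interval

    def __post_init__(self) -> None:
        validate_interval(self.range_a, what=f"{self.id_a}/{self.id_b} range_a")
        validate_interval(self.range_b, what=f"{self.id_a}/{self.id_b} range_b")


@dataclass(frozen=True)
class DomainAnnotation:
    """An externally produced domain/motif annotation on one protein."""

    protein_id: str
    accession: str
    name: str
    range: Interval

    def __post_init__(self) -> None:
        validate_interval(self.range, what=f"{self.protein_id} annotation {self.accession}")


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _int_field(value: str, path: str | Path, lineno: int, col: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: column {col}: not an integer: {value!r}"
        ) from None


def read_fasta(path: str | Path) -> dict[str, Protein]:
    """Read a FASTA file into an id -> Protein mapping.

    Sequences are upper-cased; duplicate ids and illegal residues are
    rejected.
    """
    proteome: dict[str, Protein] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if record.id in proteome:
            raise FormatError(f"{path}: duplicate id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {record.id!r} has empty sequence")
        proteome[record.id] = Protein(record.id, seq)
    return proteome


def read_pairs(path: str | Path, proteome: Mapping[str, Protein]) -> InteractionDB:
    """Read a 2-column TSV of interacting protein ids.

    (A,B) and (B,A) collapse to one unordered pair. Ids missing from the
    proteome are skipped with a logged count — public pair lists routinely
    contain ids absent from the sequence file.
    """
    db = InteractionDB(proteome=proteome)
    skipped = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        a, b = fields
        if a not in proteome or b not in proteome:
            skipped += 1
            continue
        db.add(a, b)
    if skipped:
        logger.warning("%s: skipped %d pair(s) with unknown protein ids", path, skipped)
    return db


def read_lab_sites(path: str | Path) -> list[LabSitePair]:
    """Read a 6-column TSV: idA, idB, startA, endA, startB, endB.

    Coordinates are 1-based inclusive positive integers; records with
    start > end are rejected as degenerate.
    """
    sites: list[LabSitePair] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(
                f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
            )
        id_a, id_b = fields[0], fields[1]
        coords = [_int_field(v, path, lineno, c)
                  for v, c in zip(fields[2:], ("startA", "endA", "startB", "endB"))]
        try:
            sites.append(LabSitePair(id_a, id_b, (coords[0], coords[1]),
                                     (coords[2], coords[3])))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return sites


def read_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Read a 5-column TSV: protein_id, accession, name, start, end."""
    annotations: list[DomainAnnotation] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(
                f"{path}:{lineno}: expected 5 tab-separated columns, got {len(fields)}"
            )
        pid, acc, name = fields[0], fields[1], fields[2]
        start = _int_field(fields[3], path, lineno, "start")
        end = _int_field(fields[4], path, lineno, "end")
        try:
            annotations.append(DomainAnnotation(pid, acc, name, (start, end)))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return annotations


PREDICTION_COLUMNS = (
    "idA", "idB", "rank", "peak_height", "startA", "endA", "startB", "endB"
)


def write_predictions(
    predictions: Mapping[tuple[str, str], Iterable],
    path: str | Path,
) -> None:
    """Write ranked site predictions as TSV, ordered by pair then rank.

    ``predictions`` maps (idA, idB) to SitePrediction lists (see
    :mod:`pipesites.sites`).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for (id_a, id_b) in sorted(predictions):
            preds = sorted(predictions[(id_a, id_b)], key=lambda p: p.rank)
            for p in preds:
                row = (id_a, id_b, p.rank, p.peak.height,
                       p.range_a[0], p.range_a[1], p.range_b[0], p.range_b[1])
                fh.write("\t".join(str(x) for x in row) + "\n")


def read_predictions(path: str | Path) -> dict[tuple[str, str], list]:
    """Read a predictions TSV written by :func:`write_predictions`."""
    from .sites import Peak, SitePrediction  # local import avoids a cycle

    out: dict[tuple[str, str], list] = {}
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != PREDICTION_COLUMNS:
                raise FormatError(f"{path}:{lineno}: unexpected header {fields!r}")
            header_seen = True
            continue
        if len(fields) != len(PREDICTION_COLUMNS):
            raise FormatError(
                f"{path}:{lineno}: expected {len(PREDICTION_COLUMNS)} columns"
            )
        id_a, id_b = fields[0], fields[1]
        rank, height, sa, ea, sb, eb = (
            _int_field(v, path, lineno, c)
            for v, c in zip(fields[2:], PREDICTION_COLUMNS[2:])
        )
        pred = SitePrediction(
            rank=rank,
            peak=Peak(i=sa, j=sb, height=height),
            rect=(sa, ea, sb, eb),
            range_a=(sa, ea),
            range_b=(sb, eb),
        )
        out.setdefault((id_a, id_b), []).append(pred)
    return out
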