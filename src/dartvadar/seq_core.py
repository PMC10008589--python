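"""Sequence and annotation primitives shared by all design and analysis modules.

Sequences are stored internally in the DNA alphabet (``A/C/G/T/N``); RNA
input (``U``) is accepted everywhere and normalised to ``T``, and any sequence
can be rendered back as RNA with :func:`as_rna`.  Coordinates are 0-based
half-open internally; user-facing positions are 1-based and anchored at the
start codon when a CDS is annotated (the A of ``ATG`` is position +1), which
is the convention used to name editable sites such as ``CCA60``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Localization",
    "Region",
    "RegionKind",
    "Transcript",
    "ValidationError",
    "as_rna",
    "codon_index",
    "read_annotation",
    "read_fasta",
    "revcomp",
    "translate",
    "write_fasta",
]

_VALID_BASES = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when a sequence, region table or annotation violates an invariant."""


class RegionKind(str, Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    CDS = "cds"
    THREE_PRIME_UTR = "three_prime_utr"


class Localization(str, Enum):
    CYTOPLASMIC = "cytoplasmic"
    NUCLEAR = "nuclear"
    UNKNOWN = "unknown"


#: aliases accepted in annotation files (GFF3 feature types and common spellings)
_KIND_ALIASES = {
    "cds": RegionKind.CDS,
    "five_prime_utr": RegionKind.FIVE_PRIME_UTR,
    "5utr": RegionKind.FIVE_PRIME_UTR,
    "5'utr": RegionKind.FIVE_PRIME_UTR,
    "three_prime_utr": RegionKind.THREE_PRIME_UTR,
    "3utr": RegionKind.THREE_PRIME_UTR,
    "3'utr": RegionKind.THREE_PRIME_UTR,
}


@dataclass(frozen=True)
class Region:
    """An annotated interval on a transcript, 0-based half-open."""

    kind: RegionKind
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"region {self.kind.value} [{self.start}, {self.end}) is empty or negative"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def normalize_seq(seq: str) -> str:
    """Uppercase, map RNA U to DNA T, and reject characters outside A/C/G/T/N."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return s


@dataclass
class Transcript:
    """A (spliced) transcript sequence with optional region annotation.

    Parameters
    ----------
    id:
        Record identifier.
    seq:
        Nucleotide sequence; stored as DNA (``U`` accepted and normalised).
    regions:
        Non-overlapping, sorted :class:`Region` list covering at most the
        sequence.  A CDS region, if present, must have length a positive
        multiple of 3.
    localization:
        Subcellular localization of the RNA; nuclear transcripts are not
        usable sensor targets (editing is cytoplasmic).
    secreted:
        True when the encoded product is ER-targeted/secreted, which makes
        its coding sequence ribosome-sparse and a favourable target context.
    """

    id: str
    seq: str
    regions: list[Region] = field(default_factory=list)
    localization: Localization = Localization.UNKNOWN
    secreted: bool = False

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if isinstance(self.localization, str):
            self.localization = Localization(self.localization)
        self.regions = sorted(self.regions, key=lambda r: r.start)
        self._validate_regions()

    def _validate_regions(self) -> None:
        prev_end = 0
        for region in self.regions:
            if region.start < prev_end:
                raise ValidationError(
                    f"{self.id}: regions overlap or are unsorted at {region.start}"
                )
            if region.end > len(self.seq):
                raise ValidationError(
                    f"{self.id}: region {region.kind.value} [{region.start}, {region.end})"
                    f" extends past sequence end {len(self.seq)}"
                )
            prev_end = region.end
        for region in self.regions:
            if region.kind is RegionKind.CDS and (region.end - region.start) % 3 != 0:
                raise ValidationError(
                    f"{self.id}: CDS length {region.end - region.start} is not a multiple of 3"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def cds(self) -> Region | None:
        for region in self.regions:
            if region.kind is RegionKind.CDS:
                return region
        return None

    @property
    def cds_start(self) -> int | None:
        """0-based transcript offset of the A of the start codon, if annotated."""
        cds = self.cds
        return None if cds is None else cds.start

    def region_at(self, pos: int) -> Region | None:
        for region in self.regions:
            if region.contains(pos):
                return region
        return None

    def anchored_position(self, offset: int) -> int:
        """1-based position of a transcript offset, start-codon-anchored.

        With an annotated CDS the A of the start codon is +1 (offsets 5' of
        it come out zero or negative); without a CDS this is the plain
        1-based transcript position.
        """
        start = self.cds_start
        if start is None:
            return offset + 1
        return offset - start + 1

    def offset_of_cds_position(self, cds_pos_1based: int) -> int:
        """Transcript offset (0-based) of a 1-based CDS coordinate like c.658."""
        start = self.cds_start
        if start is None:
            raise ValidationError(f"{self.id}: no CDS annotated; c. coordinates undefined")
        if cds_pos_1based < 1:
            raise ValidationError(f"c.{cds_pos_1based}: CDS positions are >= 1")
        offset = start + cds_pos_1based - 1
        cds = self.cds
        assert cds is not None
        if offset >= cds.end:
            raise ValidationError(
                f"c.{cds_pos_1based} lies past the annotated CDS end ({cds.end - start})"
            )
        return offset

    def with_substitution(self, offset: int, base: str) -> "Transcript":
        """Copy of this transcript with a single base replaced."""
        base = normalize_seq(base)
        if len(base) != 1:
            raise ValidationError("substitution must be a single base")
        if not (0 <= offset < len(self.seq)):
            raise ValidationError(f"substitution offset {offset} out of range")
        new_seq = self.seq[:offset] + base + self.seq[offset + 1 :]
        return replace(self, seq=new_seq, regions=list(self.regions))


def as_rna(seq: str) -> str:
    """Render a DNA-alphabet sequence as RNA (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; N maps to N)."""
    s = normalize_seq(seq)
    return s.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate with the standard genetic code; stops are ``*``, N-codons ``X``.

    The trailing partial codon (if any) is ignored.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    s = normalize_seq(seq)[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate(table=1))


def codon_index(cds_position_1based: int) -> int:
    """Codon number (1-based) of a 1-based CDS nucleotide position.

    c.658 falls in codon 220 — the arithmetic behind mapping an SNV such as
    a T>C at c.658 onto its affected residue.
    """
    if cds_position_1based < 1:
        raise ValueError("CDS positions are 1-based and >= 1")
    return math.ceil(cds_position_1based / 3)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a (multi-)FASTA file into :class:`Transcript` records.

    U is normalised to T and case is normalised; regions are left empty
    (attach them with :func:`read_annotation`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:  # name the offending line before handing to the parser
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValidationError(
                        f"{path.name}:{lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                    )
                break
    transcripts: list[Transcript] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            transcripts.append(Transcript(id=record.id, seq=str(record.seq)))
    except ValidationError:
        raise
    except Exception as exc:  # malformed record
        raise ValidationError(f"{path}: FASTA parse error: {exc}") from exc
    return transcripts


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, rna: bool = False) -> None:
    """Write ``(id, seq)`` pairs as FASTA; set ``rna=True`` to render with U."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            out = as_rna(seq) if rna else seq
            fh.write(f">{rec_id}\n")
            for i in range(0, len(out), 70):
                fh.write(out[i : i + 70] + "\n")


def _parse_kind(raw: str) -> RegionKind:
    key = raw.strip().lower()
    if key not in _KIND_ALIASES:
        raise ValidationError(f"unknown region kind {raw!r}")
    return _KIND_ALIASES[key]


def _read_tsv_regions(path: Path) -> dict[str | None, list[Region]]:
    """3-column dialect ``kind<TAB>start<TAB>end`` (1-based inclusive), or
    4-column ``transcript_id<TAB>kind<TAB>start<TAB>end``."""
    by_id: dict[str | None, list[Region]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 3:
                tid: str | None = None
                kind_raw, start_raw, end_raw = fields
            elif len(fields) == 4:
                tid, kind_raw, start_raw, end_raw = fields
            else:
                raise ValidationError(f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
            try:
                start, end = int(start_raw), int(end_raw)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            # 1-based inclusive file coordinates -> 0-based half-open
            by_id.setdefault(tid, []).append(Region(_parse_kind(kind_raw), start - 1, end))
    return by_id


def _read_gff3_regions(path: Path) -> dict[str | None, list[Region]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_id: dict[str | None, list[Region]] = {}
    wanted = {"CDS", "five_prime_UTR", "three_prime_UTR"}
    for feature in db.all_features():
        if feature.featuretype not in wanted:
            continue
        kind = _parse_kind(feature.featuretype)
        by_id.setdefault(feature.seqid, []).append(Region(kind, feature.start - 1, feature.end))
    return by_id


def read_annotation(path: str | Path, transcripts: Sequence[Transcript]) -> list[Transcript]:
    """Attach regions from a GFF3 file or a 3/4-column TSV region table.

    File coordinates are 1-based inclusive (GFF3 convention); they are
    converted to 0-based half-open and all :class:`Transcript` invariants
    are enforced.  Returns new Transcript objects; inputs are not mutated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        by_id = _read_gff3_regions(path)
    else:
        by_id = _read_tsv_regions(path)

    out: list[Transcript] = []
    for t in transcripts:
        regions = by_id.get(t.id)
        if regions is None and len(transcripts) == 1:
            regions = by_id.get(None)
        out.append(
            replace(t, regions=list(regions) if regions else list(t.regions))
        )
    return out
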