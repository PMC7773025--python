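"""Reference sequences, regions and strand conventions.

Coordinates are 1-based with both ends inclusive throughout the package
("position 294 to 432" names a 139-nt interval). Strands are labelled
``sense`` (the reference/transcript orientation) and ``antisense``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError

SENSE = "sense"
ANTISENSE = "antisense"

_ACGT = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named ACGT reference (e.g. the GFP transgene of the reporter line)."""

    name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise CoordinateError("reference sequence must be non-empty")
        if not set(self.sequence) <= _ACGT:
            bad = sorted(set(self.sequence) - _ACGT)
            raise CoordinateError(f"reference restricted to ACGT, found {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Substring at 1-based inclusive [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(
                f"[{start}, {end}] outside reference of length {self.length}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive interval on a reference."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"region {self.name!r}: need 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def validate_against(self, ref: ReferenceSequence) -> None:
        if self.end > ref.length:
            raise CoordinateError(
                f"region {self.name!r} ends at {self.end}, past reference "
                f"length {ref.length}"
            )


def derive_flanks(trigger: Region, ref_length: int) -> list[Region]:
    """5'/3' regions flanking the trigger: [1, start-1] and [end+1, L].

    Empty flanks (trigger touching a reference end) are omitted.
    """
    flanks = []
    if trigger.start > 1:
        flanks.append(Region("flank5", 1, trigger.start - 1))
    if trigger.end < ref_length:
        flanks.append(Region("flank3", trigger.end + 1, ref_length))
    return flanks


def assign_region(
    position: int, regions: list[Region], outside_label: str = "outside"
) -> str:
    for region in regions:
        if region.contains(position):
            return region.name
    return outside_label


def write_fasta(ref: ReferenceSequence, path: str | Path) -> None:
    record = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceSequence:
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceSequence(record.id, str(record.seq).upper())


def read_regions_tsv(path: str | Path) -> list[Region]:
    """Region file: tab-separated ``name  start  end`` (1-based inclusive).

    Lines starting with ``#`` are comments; a header line dialect note is
    conventional but not required.
    """
    regions = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":
            continue
        regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_regions_tsv(regions: list[Region], path: str | Path) -> None:
    lines = ["# 1-based inclusive coordinates", "name\tstart\tend"]
    lines += [f"{r.name}\t{r.start}\t{r.end}" for r in regions]
    Path(path).write_text("\n".join(lines) + "\n")
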