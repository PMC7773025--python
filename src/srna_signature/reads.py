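"""Small-RNA reads and FASTQ I/O.

Simulated FASTQ uses constant quality ``I`` (Phred 40): downstream
analysis never consults qualities, only sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class SmallRNARead:
    """One sequenced small-RNA read (possibly pre-trimming)."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def write_fastq(reads: list[SmallRNARead], path: str | Path) -> None:
    """Write 4-line FASTQ records, Phred+33, constant quality."""
    records = []
    for read in reads:
        record = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        record.letter_annotations["phred_quality"] = [40] * read.length
        records.append(record)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[SmallRNARead]:
    return [
        SmallRNARead(record.id, str(record.seq).upper())
        for record in SeqIO.parse(str(path), "fastq")
    ]
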