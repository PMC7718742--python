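"""Reading and writing sequence files.

FASTA is read and written; FASTQ is read (qualities are discarded — the
pipeline only consumes base calls). Gzip-compressed input is handled
transparently. Sequences are uppercased and any character outside
``{A, C, G, T, N}`` (IUPAC ambiguity codes, gap characters, ...) is
normalized to ``N`` so that downstream k-mer extraction simply skips it.

Record ids are the first whitespace-delimited token of the header line,
matching the convention of common assemblers and keeping report keys
join-safe.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Sequence, Union

__all__ = ["SeqRecord", "read_fasta", "read_reads", "write_fasta", "FormatError"]

PathLike = Union[str, Path]

# translate: keep A/C/G/T, uppercase a/c/g/t, everything else -> N
_NORMALIZE = bytes.maketrans(
    bytes(range(256)),
    bytes(
        b"ACGT"[b"ACGT".index(bytes([c]).upper())]
        if bytes([c]).upper() in (b"A", b"C", b"G", b"T")
        else ord("N")
        for c in range(256)
    ),
)


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: PathLike) -> IO[bytes]:
    """Open ``path`` for binary reading, transparently decompressing gzip."""
    path = Path(path)
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(handle, "rb")  # type: ignore[return-value]
    return handle


def _normalize(raw: bytes) -> str:
    return raw.translate(_NORMALIZE).decode("ascii")


def _iter_fasta(handle: IO[bytes], source: str) -> Iterator[SeqRecord]:
    rec_id: str | None = None
    chunks: List[bytes] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip(b"\r\n")
        if not line:
            continue
        if line.startswith(b">"):
            if rec_id is not None:
                yield _make_record(rec_id, chunks, source)
            rec_id = line[1:].split(None, 1)[0].decode("ascii") if line[1:] else ""
            if not rec_id:
                raise FormatError(f"{source}: empty FASTA header at line {lineno}")
            chunks = []
        else:
            if rec_id is None:
                raise FormatError(
                    f"{source}: sequence data before any FASTA header at line {lineno}"
                )
            chunks.append(line)
    if rec_id is not None:
        yield _make_record(rec_id, chunks, source)


def _make_record(rec_id: str, chunks: List[bytes], source: str) -> SeqRecord:
    seq = _normalize(b"".join(chunks))
    if not seq:
        raise FormatError(f"{source}: record {rec_id!r} has an empty sequence")
    return SeqRecord(rec_id, seq)


def read_fasta(path: PathLike) -> List[SeqRecord]:
    """Read a (possibly gzipped) FASTA file into a list of records.

    Ids must be unique within the file; sequences are normalized as
    described in the module docstring.
    """
    source = str(path)
    with _open_text(path) as handle:
        records = list(_iter_fasta(handle, source))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{source}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
    return records


def _iter_fastq(handle: IO[bytes], source: str) -> Iterator[SeqRecord]:
    lineno = 0
    while True:
        header = handle.readline()
        lineno += 1
        if not header:
            return
        header = header.rstrip(b"\r\n")
        if not header:
            continue
        if not header.startswith(b"@"):
            raise FormatError(
                f"{source}: expected '@' FASTQ header at line {lineno}, got {header[:20]!r}"
            )
        rec_id = header[1:].split(None, 1)[0].decode("ascii") if header[1:] else ""
        if not rec_id:
            raise FormatError(f"{source}: empty FASTQ header at line {lineno}")
        seq_line = handle.readline().rstrip(b"\r\n")
        plus = handle.readline()
        qual_line = handle.readline().rstrip(b"\r\n")
        if not plus.startswith(b"+"):
            raise FormatError(f"{source}: missing '+' separator at line {lineno + 2}")
        if len(seq_line) != len(qual_line):
            raise FormatError(
                f"{source}: record {rec_id!r} at line {lineno}: sequence length "
                f"{len(seq_line)} != quality length {len(qual_line)}"
            )
        lineno += 3
        if not seq_line:
            raise FormatError(f"{source}: record {rec_id!r} has an empty sequence")
        yield SeqRecord(rec_id, _normalize(seq_line))


def read_reads(path: PathLike) -> List[SeqRecord]:
    """Read sequencing reads from FASTQ or FASTA (optionally gzipped).

    The format is autodetected from the first non-blank byte (``@`` for
    FASTQ, ``>`` for FASTA). Quality strings are discarded.
    """
    source = str(path)
    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == b">":
            return list(_iter_fasta(handle, source))
        if first == b"@":
            return list(_iter_fastq(handle, source))
        raise FormatError(f"{source}: not FASTA or FASTQ (first byte {first!r})")


def write_fasta(records: Iterable[SeqRecord], path: PathLike, width: int = 80) -> None:
    """Write records as FASTA with ``width``-column line wrapping."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width])
                out.write("\n")


def write_fastq(records: Iterable[SeqRecord], path: PathLike, quality: str = "I") -> None:
    """Write records as FASTQ with a constant quality character."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{quality * len(rec.seq)}\n")


def total_bases(records: Sequence[SeqRecord]) -> int:
    return sum(len(r) for r in records)
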