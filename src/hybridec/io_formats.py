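"""Sequence file I/O and the serialized k-mer graph format.

FASTA/FASTQ parsing is delegated to Biopython; gzip compression is handled
transparently for any filename ending in ``.gz``. The de Bruijn graph is
dumped as a versioned, tab-separated plain-text table (one vertex per line)
so that it stays inspectable with standard shell tools.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParameterError, ParseError, GraphFormatError

GRAPH_MAGIC = "#hybridec-dbg"
GRAPH_VERSION = "v1"

_FASTA_EXTS = {".fa", ".fasta", ".fna", ".ffn", ".frn"}
_FASTQ_EXTS = {".fq", ".fastq"}


@dataclass
class ReadRecord:
    """One sequencing read.

    ``quality`` is the raw Sanger-encoded quality string; it is carried
    through unchanged and never interpreted.
    """

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _strip_gz(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".gz" else path


def detect_format(path: str | Path) -> str:
    """Guess fasta/fastq from the extension, falling back to the first byte."""
    path = Path(path)
    ext = _strip_gz(path).suffix.lower()
    if ext in _FASTA_EXTS:
        return "fasta"
    if ext in _FASTQ_EXTS:
        return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot detect sequence format (first byte {first!r})")


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[ReadRecord]:
    """Stream records from a FASTA/FASTQ file (optionally gzipped).

    Records are yielded in file order with sequences upper-cased. Duplicate
    identifiers within one file raise :class:`ParseError`, as do malformed
    records (e.g. a FASTQ entry whose quality string length differs from its
    sequence length).
    """
    if format not in ("fasta", "fastq", "auto"):
        raise ParameterError(f"unknown format {format!r}")
    fmt = detect_format(path) if format == "auto" else format
    seen: set[str] = set()
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, fmt)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            quality = None
            if fmt == "fastq":
                quality = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield ReadRecord(id=rec.id, sequence=str(rec.seq), quality=quality)


def write_sequences(
    records: Iterable[ReadRecord], path: str | Path, format: str = "fasta"
) -> int:
    """Write records as FASTA or FASTQ; returns the number written.

    FASTQ output requires a quality string. If the first record carries no
    quality, the whole file is emitted as FASTA with a warning; a missing
    quality appearing later in the stream is an error.
    """
    if format not in ("fasta", "fastq"):
        raise ParameterError(f"unknown output format {format!r}")
    records = iter(records)
    first = next(records, None)
    if format == "fastq" and first is not None and first.quality is None:
        warnings.warn(
            f"{path}: FASTQ requested but records carry no quality; writing FASTA",
            stacklevel=2,
        )
        format = "fasta"

    def as_seqrecord(rec: ReadRecord) -> SeqRecord:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        if format == "fastq":
            if rec.quality is None:
                raise ParameterError(
                    f"record {rec.id!r} has no quality string (FASTQ output)"
                )
            if len(rec.quality) != len(rec.sequence):
                raise ParseError(f"record {rec.id!r}: quality/sequence length mismatch")
            sr.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in rec.quality
            ]
        return sr

    n = 0
    with _open_text(path, "wt") as fh:
        if first is not None:
            for rec in _chain_one(first, records):
                SeqIO.write(as_seqrecord(rec), fh, format)
                n += 1
    return n


def _chain_one(first: ReadRecord, rest: Iterator[ReadRecord]) -> Iterator[ReadRecord]:
    yield first
    yield from rest


def serialize_graph(graph, path: str | Path) -> None:
    """Dump a :class:`~hybridec.dbg.DeBruijnGraph` as versioned TSV.

    Header line: ``#hybridec-dbg\tv1\tk=<k>\tcanonical=<0|1>`` followed by one
    line per vertex: kmer, count, in-edge characters, out-edge characters
    (edge sets sorted; ``-`` when empty). Vertices are written in
    lexicographic order so equal graphs serialize identically.
    """
    with _open_text(path, "wt") as fh:
        fh.write(
            f"{GRAPH_MAGIC}\t{GRAPH_VERSION}\tk={graph.k}\t"
            f"canonical={int(graph.canonical)}\n"
        )
        for kmer in sorted(graph.vertices):
            v = graph.vertices[kmer]
            ins = "".join(sorted(v.in_edges)) or "-"
            outs = "".join(sorted(v.out_edges)) or "-"
            fh.write(f"{kmer}\t{v.count}\t{ins}\t{outs}\n")


def deserialize_graph(path: str | Path):
    """Inverse of :func:`serialize_graph`; validates header and every line."""
    from .dbg import DeBruijnGraph, KmerVertex

    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if len(fields) != 4 or fields[0] != GRAPH_MAGIC:
            raise GraphFormatError(f"bad header {header!r}", line_number=1)
        if fields[1] != GRAPH_VERSION:
            raise GraphFormatError(
                f"unsupported version {fields[1]!r} (expected {GRAPH_VERSION})",
                line_number=1,
            )
        try:
            k = int(fields[2].removeprefix("k="))
            canonical = bool(int(fields[3].removeprefix("canonical=")))
        except ValueError as exc:
            raise GraphFormatError(f"bad header {header!r}", line_number=1) from exc

        graph = DeBruijnGraph(k=k, canonical=canonical)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise GraphFormatError(
                    f"expected 4 tab-separated fields, got {len(parts)}",
                    line_number=lineno,
                )
            kmer, count_s, ins, outs = parts
            if len(kmer) != k or any(c not in "ACGT" for c in kmer):
                raise GraphFormatError(f"bad k-mer {kmer!r}", line_number=lineno)
            try:
                count = int(count_s)
            except ValueError as exc:
                raise GraphFormatError(
                    f"bad count {count_s!r}", line_number=lineno
                ) from exc
            if count < 1:
                raise GraphFormatError(f"count {count} < 1", line_number=lineno)
            in_edges = set(ins) if ins != "-" else set()
            out_edges = set(outs) if outs != "-" else set()
            if not (in_edges <= set("ACGT") and out_edges <= set("ACGT")):
                raise GraphFormatError("bad edge characters", line_number=lineno)
            if kmer in graph.vertices:
                raise GraphFormatError(f"duplicate k-mer {kmer!r}", line_number=lineno)
            graph.vertices[kmer] = KmerVertex(
                kmer=kmer, count=count, in_edges=in_edges, out_edges=out_edges
            )
        graph.total_instances = sum(v.count for v in graph.vertices.values())
    return graph
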