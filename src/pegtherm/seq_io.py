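"""Sequence primitives and FASTA/FASTQ I/O shared by all pipeline stages.

Internal coordinates are 0-based half-open throughout the package; user-facing
reports convert to 1-based inclusive. Input is case-insensitive and uppercased
on ingest. Ambiguity codes are rejected in reference sequences; ``N`` is
allowed in sequencing reads only, where it always counts as a mismatch.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "NucleicSeq",
    "ReadRecord",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

_DNA_ALPHABET = set("ACGT")
_RNA_ALPHABET = set("ACGU")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


@dataclass(frozen=True)
class NucleicSeq:
    """A validated single-stranded nucleic acid sequence.

    Parameters
    ----------
    bases :
        Sequence over {A,C,G,T} (DNA) or {A,C,G,U} (RNA). Lowercase input is
        uppercased. Must be non-empty.
    alphabet :
        ``"DNA"`` or ``"RNA"``.
    name :
        Optional identifier carried through I/O.
    """

    bases: str
    alphabet: str = "DNA"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be 'DNA' or 'RNA', got {self.alphabet!r}")
        if not self.bases:
            raise ValueError("empty sequence")
        allowed = _DNA_ALPHABET if self.alphabet == "DNA" else _RNA_ALPHABET
        bad = set(self.bases) - allowed
        if bad:
            raise ValueError(
                f"invalid {self.alphabet} character(s) {sorted(bad)} in sequence "
                f"{self.name or self.bases[:20] + '...' if len(self.bases) > 20 else self.bases!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, key) -> str:
        return self.bases[key]

    @property
    def gc_fraction(self) -> float:
        return (self.bases.count("G") + self.bases.count("C")) / len(self.bases)

    def as_rna(self, name: str | None = None) -> "NucleicSeq":
        """Same strand transcribed to RNA (T→U)."""
        return NucleicSeq(self.bases.replace("T", "U"), "RNA", name if name is not None else self.name)

    def as_dna(self, name: str | None = None) -> "NucleicSeq":
        """Same strand back-transcribed to DNA (U→T)."""
        return NucleicSeq(self.bases.replace("U", "T"), "DNA", name if name is not None else self.name)


def revcomp(seq: NucleicSeq) -> NucleicSeq:
    """Reverse complement in the same alphabet. Involution: revcomp(revcomp(x)) == x."""
    table = _DNA_COMPLEMENT if seq.alphabet == "DNA" else _RNA_COMPLEMENT
    return NucleicSeq(seq.bases.translate(table)[::-1], seq.alphabet, seq.name)


def _revcomp_str(bases: str, alphabet: str = "DNA") -> str:
    table = _DNA_COMPLEMENT if alphabet == "DNA" else _RNA_COMPLEMENT
    return bases.translate(table)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read: DNA bases, Phred qualities, optional 15-base UMI.

    ``N`` is permitted in ``bases`` (counts as mismatch downstream). The UMI,
    when present, has length exactly ``15``.
    """

    read_id: str
    bases: str
    quals: list[int] = field(default_factory=list)
    umi: str | None = None

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        bad = set(self.bases) - (_DNA_ALPHABET | {"N"})
        if bad:
            raise ValueError(f"read {self.read_id}: invalid character(s) {sorted(bad)}")
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )
        if self.umi is not None and len(self.umi) != 15:
            raise ValueError(f"read {self.read_id}: UMI length {len(self.umi)} != 15")

    def __len__(self) -> int:
        return len(self.bases)


PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike, alphabet: str = "DNA") -> list[NucleicSeq]:
    """Read all records of a FASTA file (gzip transparent) as ``NucleicSeq``."""
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append(NucleicSeq(str(rec.seq), alphabet, rec.id))
    return out


def write_fasta(seqs: Iterable[NucleicSeq], path: PathLike) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.name or f"seq{i + 1}", description="") for i, s in enumerate(seqs)]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: PathLike) -> Iterator[ReadRecord]:
    """Stream 4-line Phred+33 FASTQ records (gzip transparent).

    Malformed records raise ``ValueError`` naming the (1-based) line at which
    the offending record starts.
    """
    with _open_text(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(qual) != len(seq):
                    raise ValueError(
                        f"{path}: line {4 * n + 1}: quality length {len(qual)} != "
                        f"sequence length {len(seq)} for read {title.split()[0]}"
                    )
                yield ReadRecord(title.split()[0], seq, [ord(c) - 33 for c in qual])
                n += 1
        except ValueError as exc:
            if "line" in str(exc):
                raise
            raise ValueError(f"{path}: malformed FASTQ record starting at line {4 * n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: PathLike) -> None:
    """Write 4-line Phred+33 FASTQ. Byte-identical round trip with read_fastq."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{''.join(chr(q + 33) for q in r.quals)}\n")


def fastq_bytes(reads: Iterable[ReadRecord]) -> bytes:
    """FASTQ serialisation as bytes (for reproducibility checks)."""
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.bases}\n+\n{''.join(chr(q + 33) for q in r.quals)}\n")
    return buf.getvalue().encode()
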