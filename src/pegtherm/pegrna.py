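"""pegRNA construction from a target locus and an edit specification.

Geometry (SpCas9-H840A only): the 20-nt protospacer sits next to an NGG PAM on
the non-target strand; the nickase cuts that strand between protospacer
positions 17 and 18. Edit positions use the nick-relative "+N" convention
(+1 = first nucleotide 3' of the nick on the non-target strand, so +1..+3 are
protospacer positions 18-20 and +4..+6 are the PAM). The pegRNA is assembled
5'->3' as spacer - scaffold - RTT - PBS [- 3' motif]:

* PBS = reverse complement (as RNA) of protospacer positions 18-L .. 17, i.e.
  complementary to the last L nt of the nicked non-target strand.
* RTT = reverse complement (as RNA) of the *edited* non-target strand from the
  nick through the edit plus a homology arm; its 3' terminus abuts the PBS and
  templates position +1 first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .seq_io import NucleicSeq, _revcomp_str

__all__ = [
    "SGRNA_SCAFFOLD",
    "TEVOPREQ1",
    "TargetLocus",
    "EditSpec",
    "PegRNA",
    "NickingGuide",
    "nick_position",
    "derive_pbs",
    "derive_rtt",
    "assemble",
]

# Canonical S. pyogenes sgRNA scaffold (spacer and 3' extension excluded).
SGRNA_SCAFFOLD = "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC"

# tevopreQ1 pseudoknot used to 3'-end-protect epegRNAs.
TEVOPREQ1 = "CGCGGUUCUAUCUAGUUACGCGUUAAACCAACUAGAA"

PROTOSPACER_LEN = 20
NICK_OFFSET = 17  # nick between protospacer positions 17 and 18 (1-based)
MAX_PBS_LEN = 17
MIN_5P_FLANK = 34  # max PBS (17) + margin, per the locus contract


@dataclass(frozen=True)
class TargetLocus:
    """A genomic window with one SpCas9 protospacer.

    ``window`` is the top strand; ``protospacer_start`` is the 0-based offset
    of the 20-nt protospacer *on the protospacer strand* (the window itself
    for '+', its reverse complement for '-'). The PAM immediately 3' of the
    protospacer must match NGG.
    """

    window: NucleicSeq
    protospacer_start: int
    strand: Literal["+", "-"] = "+"
    pam: str = ""

    def __post_init__(self) -> None:
        if self.window.alphabet != "DNA":
            raise ValueError("locus window must be DNA")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        seq = self.protospacer_strand_seq
        s = self.protospacer_start
        if s < 0 or s + PROTOSPACER_LEN + 3 > len(seq):
            raise ValueError("window does not contain protospacer + PAM")
        if s < MIN_5P_FLANK:
            raise ValueError(
                f"need >= {MIN_5P_FLANK} nt of flank 5' of the protospacer, got {s}"
            )
        pam = seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + 3]
        if pam[1:] != "GG":
            raise ValueError(f"PAM {pam!r} does not match NGG")
        object.__setattr__(self, "pam", pam)

    @property
    def protospacer_strand_seq(self) -> str:
        """The strand carrying the protospacer (= the non-target strand), 5'->3'."""
        if self.strand == "+":
            return self.window.bases
        return _revcomp_str(self.window.bases)

    @property
    def protospacer(self) -> str:
        s = self.protospacer_start
        return self.protospacer_strand_seq[s : s + PROTOSPACER_LEN]

    def downstream_of_nick(self) -> str:
        """Non-target strand from the nick to the end of the window, 5'->3'.

        Index 0 is position +1.
        """
        return self.protospacer_strand_seq[nick_position(self) :]


def nick_position(locus: TargetLocus) -> int:
    """0-based half-open boundary of the SpCas9-H840A nick on the non-target strand.

    Returned in protospacer-strand coordinates: the nick falls between indices
    ``pos - 1`` and ``pos`` (i.e. after protospacer position 17, 1-based).
    """
    return locus.protospacer_start + NICK_OFFSET


@dataclass(frozen=True)
class EditSpec:
    """Intended edit in nick-relative coordinates on the non-target strand.

    ``position`` >= +1; ``ref`` is empty for insertions, ``alt`` empty for
    deletions; substitutions have ``len(ref) == len(alt) >= 1``.
    """

    kind: Literal["substitution", "insertion", "deletion"]
    position: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.position < 1:
            raise ValueError(f"edit position must be >= +1, got {self.position}")
        if self.kind == "substitution":
            if not (len(self.ref) == len(self.alt) >= 1):
                raise ValueError("substitution requires len(ref) == len(alt) >= 1")
        elif self.kind == "insertion":
            if self.ref or not self.alt:
                raise ValueError("insertion requires empty ref and non-empty alt")
        elif self.kind == "deletion":
            if self.alt or not self.ref:
                raise ValueError("deletion requires empty alt and non-empty ref")
        else:
            raise ValueError(f"unknown edit kind {self.kind!r}")

    def apply(self, downstream: str) -> tuple[str, int]:
        """Apply to the non-target strand 3' of the nick (index 0 = +1).

        Returns (edited strand, 0-based end of the edited segment on the
        edited strand). Raises on ref mismatch, reporting both sequences.
        """
        p = self.position - 1
        if self.kind in ("substitution", "deletion"):
            found = downstream[p : p + len(self.ref)]
            if found != self.ref:
                raise ValueError(
                    f"edit ref mismatch at +{self.position}: spec says {self.ref!r}, "
                    f"locus has {found!r}"
                )
        if self.kind == "substitution":
            return downstream[:p] + self.alt + downstream[p + len(self.ref) :], p + len(self.alt)
        if self.kind == "insertion":
            return downstream[:p] + self.alt + downstream[p:], p + len(self.alt)
        return downstream[:p] + downstream[p + len(self.ref) :], p


@dataclass(frozen=True)
class PegRNA:
    """Ordered pegRNA components with a coordinate map over the full molecule.

    Concatenation order is fixed: spacer - scaffold - RTT - PBS [- motif3p].
    """

    spacer: str
    scaffold: str
    rtt: str
    pbs: str
    motif3p: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        for label, part in (("spacer", self.spacer), ("scaffold", self.scaffold),
                            ("rtt", self.rtt), ("pbs", self.pbs)):
            if set(part) - set("ACGU"):
                raise ValueError(f"{label} is not RNA: {part!r}")
        if self.motif3p is not None and set(self.motif3p) - set("ACGU"):
            raise ValueError(f"motif3p is not RNA: {self.motif3p!r}")
        if len(self.spacer) != PROTOSPACER_LEN:
            raise ValueError(f"spacer must be {PROTOSPACER_LEN} nt, got {len(self.spacer)}")
        if not 1 <= len(self.pbs) <= MAX_PBS_LEN:
            raise ValueError(f"PBS length must be in [1, {MAX_PBS_LEN}], got {len(self.pbs)}")
        if not self.rtt:
            raise ValueError("RTT must be non-empty")

    @property
    def sequence(self) -> str:
        """Full 5'->3' molecule."""
        return self.spacer + self.scaffold + self.rtt + self.pbs + (self.motif3p or "")

    @property
    def boundaries(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, end) offsets of each component in ``sequence``."""
        out: dict[str, tuple[int, int]] = {}
        pos = 0
        for label, part in (("spacer", self.spacer), ("scaffold", self.scaffold),
                            ("rtt", self.rtt), ("pbs", self.pbs),
                            ("motif3p", self.motif3p or "")):
            if label == "motif3p" and self.motif3p is None:
                continue
            out[label] = (pos, pos + len(part))
            pos += len(part)
        return out

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NickingGuide:
    """PE3 nicking sgRNA: targets the strand opposite the pegRNA protospacer.

    ``offset`` is the signed distance of its nick from the pegRNA nick.
    """

    spacer: str
    offset: int

    def __post_init__(self) -> None:
        if len(self.spacer) != PROTOSPACER_LEN or set(self.spacer) - set("ACGU"):
            raise ValueError("nicking guide spacer must be 20-nt RNA")


def derive_pbs(locus: TargetLocus, L: int) -> NucleicSeq:
    """PBS of length ``L``: RNA reverse complement of protospacer positions 18-L..17.

    Complementary to the last ``L`` nt of the nicked non-target strand, so a
    PBS derived here anneals the free 3' DNA end with zero mismatches.
    """
    if not 1 <= L <= MAX_PBS_LEN:
        raise ValueError(f"PBS length must be in [1, {MAX_PBS_LEN}], got {L}")
    seg = locus.protospacer[NICK_OFFSET - L : NICK_OFFSET]
    return NucleicSeq(_revcomp_str(seg).replace("T", "U"), "RNA", f"PBS{L}")


def derive_rtt(locus: TargetLocus, edit: EditSpec, ha_len: int) -> NucleicSeq:
    """RTT: RNA reverse complement of the edited non-target strand from the nick
    through (edit end + ``ha_len``).

    The RTT 3' terminus abuts the PBS and templates position +1 first; the
    homology arm extends ``ha_len`` nt past the edit.
    """
    if ha_len < 1:
        raise ValueError("homology arm length must be >= 1")
    edited, edit_end = edit.apply(locus.downstream_of_nick())
    span = edit_end + ha_len
    if span > len(edited):
        raise ValueError(
            f"RTT span {span} exceeds available window sequence ({len(edited)} nt 3' of nick)"
        )
    return NucleicSeq(_revcomp_str(edited[:span]).replace("T", "U"), "RNA", "RTT")


def assemble(
    locus: TargetLocus,
    edit: EditSpec,
    pbs_len: int,
    ha_len: int,
    scaffold: str = SGRNA_SCAFFOLD,
    motif3p: str | None = None,
    name: str = "",
    expression_plasmid: bool = False,
) -> PegRNA:
    """Build a full pegRNA for ``locus``/``edit``.

    With ``expression_plasmid=True`` a warning is emitted when the spacer does
    not start with G (U6 transcription prefers a 5'-G); the requirement is not
    enforced because synthetic/RNP pegRNAs have no such constraint.
    """
    spacer = locus.protospacer.replace("T", "U")
    if expression_plasmid and spacer[0] != "G":
        import warnings

        warnings.warn(
            "spacer does not start with G; U6 expression plasmids prefer a 5'-G",
            stacklevel=2,
        )
    return PegRNA(
        spacer=spacer,
        scaffold=scaffold,
        rtt=derive_rtt(locus, edit, ha_len).bases,
        pbs=derive_pbs(locus, pbs_len).bases,
        motif3p=motif3p,
        name=name,
    )
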