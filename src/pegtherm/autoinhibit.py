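"""Intramolecular spacer:PBS auto-inhibition scoring and rescue-oligo design.

The pegRNA spacer and PBS are complementary by construction (both derive from
the protospacer), so the molecule can fold back on itself: PBS base i pairs
spacer position 17-i (1-based), and the duplex can propagate into the RTT's
3'-terminal <= 3 nt, which pair spacer positions 18-20 whenever the RTT
templates the unedited target there. This RNA:RNA hairpin outcompetes the
weaker PBS:target RNA:DNA hybrid and blocks R-loop formation; shortening the
PBS shrinks the duplex, which is the mechanistic basis of choosing the
shortest PBS whose target Tm matches the editing temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .pegrna import PegRNA
from .seq_io import NucleicSeq, _revcomp_str
from .thermo import DuplexTable, ThermoParams, _nn_sums, T37_K

__all__ = [
    "AutoInhibitionReport",
    "OligoSpan",
    "score_autoinhibition",
    "design_competing_oligo",
]

_RNA_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

#: PBS >= 10 nt abolished in vitro cleavage while 7-8 nt partially restored it,
#: so a contiguous duplex of >= 10 bp is flagged severe by default.
DEFAULT_SEVERITY_THRESHOLD = 10


def _wc(a: str, b: str) -> bool:
    return (a, b) in _RNA_WC


@dataclass(frozen=True)
class AutoInhibitionReport:
    """Extent and stability of the spacer:PBS(+RTT) intramolecular duplex.

    ``pbs_pairs`` counts contiguous Watson-Crick pairs anchored at spacer
    position 17 walking 5'; ``rtt_extension`` (0-3) counts pairs between the
    RTT's 3'-terminal nucleotides and spacer positions 18-20, only while
    contiguous with the PBS duplex. ``dg37_rna_rna`` is the RNA:RNA free
    energy of the paired region at 37°C (kcal/mol, 0.0 when fewer than two
    pairs exist).
    """

    pbs_pairs: int
    rtt_extension: int
    total_duplex_len: int
    dg37_rna_rna: float
    severity_flag: bool
    severity_threshold: int = DEFAULT_SEVERITY_THRESHOLD


def score_autoinhibition(
    peg: PegRNA,
    params: ThermoParams | None = None,
    severity_threshold: int = DEFAULT_SEVERITY_THRESHOLD,
) -> AutoInhibitionReport:
    """Quantify the spacer:PBS(+RTT) fold-back duplex of ``peg``.

    Pairing is strict Watson-Crick (no wobble). The RTT extension counts only
    pairs contiguous with the PBS duplex: a mismatch at the RTT/PBS junction
    (e.g. an edit at +1) zeroes it even if +2/+3 would match, because duplex
    propagation is the physical mechanism.
    """
    if params is None:
        params = ThermoParams(table=DuplexTable.RNA_RNA)
    if DuplexTable(params.table) is not DuplexTable.RNA_RNA:
        raise ValueError("auto-inhibition scoring uses the RNA_RNA table")

    spacer, pbs, rtt = peg.spacer, peg.pbs, peg.rtt

    pbs_pairs = 0
    for k in range(min(len(pbs), 17)):
        if _wc(pbs[k], spacer[16 - k]):
            pbs_pairs += 1
        else:
            break

    rtt_extension = 0
    if pbs_pairs >= 1:  # extension must be contiguous with the PBS duplex
        for j in range(min(3, len(rtt))):
            if _wc(rtt[-1 - j], spacer[17 + j]):
                rtt_extension += 1
            else:
                break

    total = pbs_pairs + rtt_extension

    if total >= 2:
        # spacer-side strand of the paired region, 5'->3'
        duplex_probe = NucleicSeq(spacer[17 - pbs_pairs : 17 + rtt_extension], "RNA")
        dh, ds = _nn_sums(duplex_probe, params)
        dg = dh - T37_K * ds / 1000.0
    else:
        dg = 0.0

    return AutoInhibitionReport(
        pbs_pairs=pbs_pairs,
        rtt_extension=rtt_extension,
        total_duplex_len=total,
        dg37_rna_rna=dg,
        severity_flag=total >= severity_threshold,
        severity_threshold=severity_threshold,
    )


class OligoSpan(str, Enum):
    PBS_ONLY = "PBS_ONLY"
    PBS_PLUS_RTT = "PBS_PLUS_RTT"


def design_competing_oligo(peg: PegRNA, span: OligoSpan = OligoSpan.PBS_PLUS_RTT) -> NucleicSeq:
    """DNA oligo exactly complementary to the pegRNA 3' extension, 5'->3'.

    Pre-annealing such an oligo sequesters the PBS(-RTT) region and restores
    Cas9 cleavage in vitro; the PBS+RTT span is the default because an oligo
    covering the PBS alone leaves the RTT/spacer homology free to pair.
    """
    span = OligoSpan(span)
    target = peg.pbs if span is OligoSpan.PBS_ONLY else peg.rtt + peg.pbs
    dna = target.replace("U", "T")
    return NucleicSeq(_revcomp_str(dna), "DNA", f"anti-{span.value}")
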