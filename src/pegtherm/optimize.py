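"""PBS-length optimization toward the editing temperature, plus PE2/PE3 dosing.

The design rule: among candidate PBS lengths, prefer the one whose predicted
PBS:nicked-target RNA:DNA hybrid Tm is closest to the temperature at which
editing will occur (37°C mammalian culture, 28.5°C zebrafish embryos, 30°C
cold shock). The objective is two-sided |Tm - T_target|; ties break toward
the shorter PBS, which carries less spacer:PBS auto-inhibition. The full
ranked candidate list is always returned, never only the winner.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .autoinhibit import AutoInhibitionReport, score_autoinhibition
from .pegrna import EditSpec, TargetLocus, assemble, derive_pbs
from .thermo import DuplexTable, ThermoParams, TmResult, tm_nearest_neighbor

__all__ = [
    "TemperaturePreset",
    "DesignCandidate",
    "StoichiometryPlan",
    "optimize_pbs",
    "candidates_frame",
    "recommend_stoichiometry",
]


class TemperaturePreset(Enum):
    """Editing-temperature presets with their target Tm in °C."""

    MAMMALIAN_37 = 37.0
    ZEBRAFISH_28_5 = 28.5
    COLD_SHOCK_30 = 30.0

    @property
    def t_target(self) -> float:
        return self.value


COLD_SHOCK_NOTE = (
    "At 30°C shorter PBS lengths are tolerated or preferred; a transient "
    "cold shock (12-16 h at 30°C post delivery) additionally raises editing "
    "rates for Tm-optimized pegRNAs."
)

PLASMID_EXPRESSION_NOTE = (
    "For unprotected, plasmid-expressed pegRNAs (subject to 3' truncation) the "
    "empirically optimal PBS is longer (~13 nt at balanced GC); this optimizer "
    "targets end-protected pegRNAs (synthetic or epegRNA)."
)


@dataclass(frozen=True)
class DesignCandidate:
    """One PBS-length option with its predicted Tm and auto-inhibition report."""

    pbs_len: int
    pbs_seq: str
    tm: TmResult
    delta_t: float
    autoinhibition: AutoInhibitionReport
    rank: int = 0
    rtt_first3_editable_hint: bool = False


def optimize_pbs(
    locus: TargetLocus,
    edit: EditSpec,
    preset: TemperaturePreset | float = TemperaturePreset.MAMMALIAN_37,
    l_range: tuple[int, int] = (4, 17),
    params: ThermoParams | None = None,
    ha_len: int = 10,
) -> list[DesignCandidate]:
    """Rank PBS lengths by closeness of hybrid Tm to the target temperature.

    Parameters
    ----------
    locus, edit :
        Target and intended edit; used to derive each candidate PBS and the
        pegRNA whose auto-inhibition is reported.
    preset :
        A :class:`TemperaturePreset` or a custom target temperature in °C.
    l_range :
        Inclusive PBS length range; default 4 (NN-model validity floor) to
        17 (longest length in routine use at A/T-rich sites).
    params :
        Thermo context; defaults to the hybrid table with package defaults.
    ha_len :
        Homology-arm length for the assembled pegRNA behind each candidate's
        auto-inhibition report (does not affect Tm or ranking beyond the
        <=3-nt RTT extension, which is ha-independent for ha_len >= 3).

    Returns
    -------
    list[DesignCandidate]
        One candidate per length, sorted by ascending ``delta_t`` with ties
        broken toward the shorter PBS; ``rank`` is 1-based.
    """
    t_target = preset.t_target if isinstance(preset, TemperaturePreset) else float(preset)
    lo, hi = l_range
    if not 1 <= lo <= hi <= 17:
        raise ValueError(f"l_range must satisfy 1 <= lo <= hi <= 17, got {l_range}")
    if params is None:
        params = ThermoParams(table=DuplexTable.RNA_DNA_HYBRID)

    # Edits within +1..+3 shrink the RTT/spacer homology; surface as a hint.
    downstream = locus.downstream_of_nick()
    edited, _ = edit.apply(downstream)
    first3_editable = edited[:3] != downstream[:3]

    out = []
    for L in range(lo, hi + 1):
        pbs = derive_pbs(locus, L)
        tm = tm_nearest_neighbor(pbs, params)
        peg = assemble(locus, edit, pbs_len=L, ha_len=ha_len)
        out.append(
            DesignCandidate(
                pbs_len=L,
                pbs_seq=pbs.bases,
                tm=tm,
                delta_t=abs(tm.tm_celsius - t_target),
                autoinhibition=score_autoinhibition(peg),
                rtt_first3_editable_hint=first3_editable,
            )
        )
    out.sort(key=lambda c: (c.delta_t, c.pbs_len))
    return [
        DesignCandidate(**{**c.__dict__, "rank": i + 1}) for i, c in enumerate(out)
    ]


def candidates_frame(candidates: list[DesignCandidate]) -> pd.DataFrame:
    """Tabular view of a ranked candidate list (one row per PBS length)."""
    return pd.DataFrame(
        {
            "rank": [c.rank for c in candidates],
            "pbs_len": [c.pbs_len for c in candidates],
            "pbs_seq": [c.pbs_seq for c in candidates],
            "tm_C": [c.tm.tm_celsius for c in candidates],
            "delta_t_C": [c.delta_t for c in candidates],
            "duplex_len": [c.autoinhibition.total_duplex_len for c in candidates],
            "dg37_rna_rna": [c.autoinhibition.dg37_rna_rna for c in candidates],
            "severe_autoinhibition": [c.autoinhibition.severity_flag for c in candidates],
        }
    )


@dataclass(frozen=True)
class StoichiometryPlan:
    """Component doses for one delivery format/cell preset.

    Units are pmol for electroporation presets and µM for embryo injection
    (``unit`` records which). ``nicking_amount`` is a (low, high) range and is
    sub-stoichiometric to the pegRNA: excess nicking sgRNA displaces the
    pegRNA from the limited prime editor protein.
    """

    format: str
    cell_preset: str
    unit: str
    pe_amount: float
    pegrna_amount: float
    nicking_amount: tuple[float, float]


# Validated dose anchors; linear scaling in pe_amount.
_RNP_PRESETS = {
    # preset: (PE pmol, pegRNA pmol, (nick low, nick high) pmol, unit)
    "standard": (50.0, 200.0, (15.0, 30.0), "pmol"),
    "fibroblast_tcell": (150.0, 600.0, (45.0, 45.0), "pmol"),
    "embryo": (6.0, 12.0, (1.2, 1.2), "uM"),  # nicking = pegRNA/10
}
_MRNA_PRESETS = {
    # preset: (mRNA ug, pegRNA pmol, (nick low, nick high) pmol)
    "standard": (1.0, 100.0, (50.0, 50.0)),
}


def recommend_stoichiometry(
    format: str, cell_preset: str, pe_amount: float
) -> StoichiometryPlan:
    """Scale validated PE2/PE3 doses linearly to ``pe_amount``.

    RNP anchors: 50 pmol PE : 200 pmol pegRNA : 15-30 pmol nicking sgRNA
    (pegRNA:PE held at 4:1); fibroblast/T-cell 150:600:45; embryo injection
    6 µM PE : 12 µM pegRNA : nicking = pegRNA/10. mRNA anchor: 1 µg PE mRNA :
    100 pmol pegRNA : 50 pmol nicking.
    """
    if pe_amount <= 0:
        raise ValueError("pe_amount must be > 0")
    fmt = format.upper()
    if fmt == "RNP":
        presets = _RNP_PRESETS
    elif fmt == "MRNA":
        presets = {k: (v[0], v[1], v[2], "ug mRNA / pmol guides") for k, v in _MRNA_PRESETS.items()}
    else:
        raise ValueError(f"unknown format {format!r}: choose RNP or mRNA")
    if cell_preset not in presets:
        raise ValueError(
            f"unknown {fmt} preset {cell_preset!r}: choose one of {sorted(presets)}"
        )
    pe0, peg0, (nlo, nhi), unit = presets[cell_preset]
    scale = pe_amount / pe0
    return StoichiometryPlan(
        format=fmt,
        cell_preset=cell_preset,
        unit=unit,
        pe_amount=pe_amount,
        pegrna_amount=peg0 * scale,
        nicking_amount=(nlo * scale, nhi * scale),
    )
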