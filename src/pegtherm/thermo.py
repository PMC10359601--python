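"""Nearest-neighbor melting-temperature engine for short duplexes.

Supports the RNA:DNA hybrid chemistry that governs PBS:nicked-target annealing
in prime editing, plus DNA:DNA and RNA:RNA parameter sets and the Wallace
base-composition rule. The duplex is assumed fully Watson-Crick paired (the
complement strand is implied), which is exactly the geometry of a PBS designed
against its own protospacer.

Model::

    Tm(K) = 1000 * dH / (dS' + R * ln(C_T / 4))

with ``dH`` (kcal/mol) and ``dS`` (cal/mol/K) the initiation-plus-stack sums
keyed on the probe strand 5'->3', ``R = 1.987`` cal/mol/K, ``C_T`` the total
strand concentration, the ``C_T/4`` factor for non-self-complementary duplexes
(PBS and target are distinct strands), and ``dS'`` the salt-corrected entropy.
Defaults (150 mM Na+, C_T = 1e-4 M, SantaLucia-1998 entropy salt correction)
are recorded in every result and are configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources

from .seq_io import NucleicSeq, revcomp

__all__ = [
    "DuplexTable",
    "SaltCorrection",
    "ThermoParams",
    "TmResult",
    "tm_nearest_neighbor",
    "tm_wallace",
    "dg37",
]

R_GAS = 1.987  # cal/(mol*K)
T37_K = 310.15


class DuplexTable(str, Enum):
    RNA_DNA_HYBRID = "RNA_DNA_HYBRID"
    DNA_DNA = "DNA_DNA"
    RNA_RNA = "RNA_RNA"


class SaltCorrection(str, Enum):
    SANTALUCIA_ENTROPY = "santalucia_entropy"  # dS += 0.368*(N-1)*ln[Na+]
    SCHILDKRAUT = "schildkraut"  # Tm += 16.6*log10[Na+]
    NONE = "none"


class TmMethod(str, Enum):
    NEAREST_NEIGHBOR = "NEAREST_NEIGHBOR"
    WALLACE = "WALLACE"


def _load_tables() -> dict:
    with resources.files("pegtherm.data").joinpath("nn_tables.json").open() as fh:
        return json.load(fh)


_TABLES_CACHE: dict | None = None


def _tables() -> dict:
    global _TABLES_CACHE
    if _TABLES_CACHE is None:
        _TABLES_CACHE = _load_tables()
    return _TABLES_CACHE


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic context for a nearest-neighbor Tm calculation.

    Parameters
    ----------
    table :
        Duplex chemistry; selects the dH/dS parameter set.
    sodium_mM :
        Monovalent cation concentration in mM (> 0).
    strand_conc_M :
        Total strand concentration C_T in mol/L (> 0).
    salt_correction :
        How ``sodium_mM`` enters the calculation.
    """

    table: DuplexTable = DuplexTable.RNA_DNA_HYBRID
    sodium_mM: float = 150.0
    strand_conc_M: float = 1e-4
    salt_correction: SaltCorrection = SaltCorrection.SANTALUCIA_ENTROPY

    def __post_init__(self) -> None:
        if self.sodium_mM <= 0:
            raise ValueError("sodium_mM must be > 0")
        if self.strand_conc_M <= 0:
            raise ValueError("strand_conc_M must be > 0")

    @property
    def dH_table(self) -> dict[str, float]:
        t = _tables()["tables"][DuplexTable(self.table).value]
        return {k: v[0] for k, v in t["stacks"].items()}

    @property
    def dS_table(self) -> dict[str, float]:
        t = _tables()["tables"][DuplexTable(self.table).value]
        return {k: v[1] for k, v in t["stacks"].items()}

    @property
    def init_terms(self) -> tuple[float, float]:
        t = _tables()["tables"][DuplexTable(self.table).value]
        return tuple(t["init"])

    def with_table(self, table: DuplexTable) -> "ThermoParams":
        return replace(self, table=table)


@dataclass(frozen=True)
class TmResult:
    """Predicted melting temperature plus the thermodynamic sums behind it.

    ``dH``/``dS``/``dG37`` are the uncorrected initiation-plus-stack sums;
    the salt correction enters ``tm_celsius`` only. Wallace-rule results carry
    no dH/dS (the rule is purely compositional).
    """

    tm_celsius: float
    method: TmMethod
    dH: float | None = None  # kcal/mol
    dS: float | None = None  # cal/(mol*K)
    dG37: float | None = None  # kcal/mol
    params_used: ThermoParams | None = None
    probe: str = ""


def _probe_key_sequence(probe: NucleicSeq, table: DuplexTable) -> str:
    """The strand on which the NN table is keyed, 5'->3'.

    The hybrid table is keyed on the RNA strand: an RNA probe is used as-is,
    while a DNA probe implies an RNA complement, whose 5'->3' sequence is the
    reverse complement of the probe transcribed to RNA.
    """
    table = DuplexTable(table)
    spec_alpha = _tables()["tables"][table.value]["probe_alphabet"]
    if table is DuplexTable.RNA_DNA_HYBRID:
        if probe.alphabet == "RNA":
            return probe.bases
        return revcomp(probe).as_rna().bases
    if probe.alphabet != spec_alpha:
        raise ValueError(
            f"table {table.value} expects a {spec_alpha} probe, got {probe.alphabet}"
        )
    return probe.bases


def _nn_sums(probe: NucleicSeq, params: ThermoParams) -> tuple[float, float]:
    """Initiation + stack + terminal-penalty sums (dH kcal/mol, dS cal/mol/K)."""
    key_seq = _probe_key_sequence(probe, params.table)
    spec = _tables()["tables"][DuplexTable(params.table).value]
    dh, ds = spec["init"]
    stacks = spec["stacks"]
    for i in range(len(key_seq) - 1):
        h, s = stacks[key_seq[i : i + 2]]
        dh += h
        ds += s
    for end in (key_seq[0], key_seq[-1]):
        pen = spec["terminal_penalties"].get(end)
        if pen is not None:
            dh += pen[0]
            ds += pen[1]
    return dh, ds


def tm_nearest_neighbor(probe: NucleicSeq, params: ThermoParams | None = None) -> TmResult:
    """Nearest-neighbor Tm of the probe against its exact Watson-Crick complement.

    Parameters
    ----------
    probe :
        RNA or DNA sequence of length >= 4 (the NN model is unreliable below
        that). For the hybrid table this is typically the RNA PBS; a DNA probe
        is accepted and keyed on its implied RNA complement.
    params :
        Thermodynamic context; package defaults when omitted.

    Returns
    -------
    TmResult
        With ``dG37 == dH - 310.15*dS/1000`` exactly.
    """
    if params is None:
        params = ThermoParams()
    if len(probe) < 4:
        raise ValueError(f"probe length {len(probe)} < 4: nearest-neighbor model unreliable")
    dh, ds = _nn_sums(probe, params)
    na_M = params.sodium_mM / 1000.0
    ds_eff = ds
    corr = SaltCorrection(params.salt_correction)
    if corr is SaltCorrection.SANTALUCIA_ENTROPY:
        ds_eff = ds + 0.368 * (len(probe) - 1) * math.log(na_M)
    tm = dh * 1000.0 / (ds_eff + R_GAS * math.log(params.strand_conc_M / 4.0)) - 273.15
    if corr is SaltCorrection.SCHILDKRAUT:
        tm += 16.6 * math.log10(na_M)
    return TmResult(
        tm_celsius=tm,
        method=TmMethod.NEAREST_NEIGHBOR,
        dH=dh,
        dS=ds,
        dG37=dh - T37_K * ds / 1000.0,
        params_used=params,
        probe=probe.bases,
    )


def tm_wallace(probe: NucleicSeq) -> TmResult:
    """Wallace rule: Tm = 4°C per G/C + 2°C per A/T(U). Compositional only."""
    gc = probe.bases.count("G") + probe.bases.count("C")
    at = len(probe) - gc
    return TmResult(tm_celsius=4.0 * gc + 2.0 * at, method=TmMethod.WALLACE, probe=probe.bases)


def dg37(probe: NucleicSeq, params: ThermoParams | None = None) -> float:
    """Duplex free energy at 37°C (kcal/mol) from the same NN sums.

    Negative values indicate a duplex stable at 37°C; more negative = more
    stable. Salt correction does not enter (dG37 is reported at the tabulated
    1 M reference state, as the underlying parameter sets are).
    """
    if params is None:
        params = ThermoParams()
    if len(probe) < 4:
        raise ValueError(f"probe length {len(probe)} < 4: nearest-neighbor model unreliable")
    dh, ds = _nn_sums(probe, params)
    return dh - T37_K * ds / 1000.0
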