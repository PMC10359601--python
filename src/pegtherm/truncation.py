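"""Small-RNA-seq 3'-truncation profiling of pegRNA/epegRNA pools.

U6-expressed pegRNAs are degraded from the 3' end, producing a ladder of
species that differ in how much of the scaffold/RTT/PBS survives; truncated
molecules still load the prime editor and compete with full-length pegRNA.
This module classifies each sequencing read by where its alignment to the
designed pegRNA ends (truncations are strictly 3', so alignment is anchored
at the reference 5' end), then counts molecules per species using the 15-base
UMI carried in the 3' ligation adapter.

Species (partitioning every read):

* ``FULL_LENGTH`` — endpoint reaches the end of the pegRNA; for epegRNA
  references an endpoint inside the 3' motif still counts as full-length of
  the pegRNA core, with a motif-truncation sub-flag.
* ``PBS_TRUNC_FUNCTIONAL`` — endpoint inside the PBS leaving >= 7 PBS nt.
* ``PBS_TRUNC_INSUFFICIENT`` — endpoint inside the PBS leaving 1-6 PBS nt.
* ``RTT_TRUNC`` — endpoint inside the RTT (or exactly at the RTT/PBS border).
* ``SCAFFOLD_TRUNC`` — endpoint inside the scaffold or spacer.
* ``UNASSIGNED`` — no adapter/UMI, alignment identity below threshold, or
  insert shorter than 15 nt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import edlib
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .pegrna import PegRNA
from .seq_io import ReadRecord

__all__ = [
    "SpeciesCategory",
    "SpeciesCall",
    "SpeciesTable",
    "Adapter3p",
    "extract_umi_and_trim",
    "classify_read",
    "categorize_endpoint",
    "dedup_and_tabulate",
    "compare_bound_vs_bulk",
    "profile_library",
]

#: Minimum PBS nucleotides for a truncated pegRNA to remain plausibly functional.
FUNCTIONAL_PBS_MIN = 7

MIN_INSERT_LEN = 15


class SpeciesCategory(str, Enum):
    FULL_LENGTH = "FULL_LENGTH"
    PBS_TRUNC_FUNCTIONAL = "PBS_TRUNC_FUNCTIONAL"
    PBS_TRUNC_INSUFFICIENT = "PBS_TRUNC_INSUFFICIENT"
    RTT_TRUNC = "RTT_TRUNC"
    SCAFFOLD_TRUNC = "SCAFFOLD_TRUNC"
    UNASSIGNED = "UNASSIGNED"


ASSIGNED_CATEGORIES = [c for c in SpeciesCategory if c is not SpeciesCategory.UNASSIGNED]


@dataclass(frozen=True)
class SpeciesCall:
    """Per-read species assignment.

    ``endpoint`` is the 0-based offset of the last aligned reference base + 1
    (``None`` for UNASSIGNED). ``motif_truncated`` marks epegRNA reads whose
    pegRNA core is intact but whose 3' motif is partially lost.
    """

    read_id: str
    category: SpeciesCategory
    endpoint: int | None = None
    umi: str | None = None
    motif_truncated: bool = False


@dataclass(frozen=True)
class Adapter3p:
    """3' ligation adapter layout: ``fixed[:umi_offset] + UMI + fixed[umi_offset:]``.

    Default layout (``umi_offset=0``) puts the UMI immediately 5' of the fixed
    adapter sequence, i.e. reads look like ``insert + UMI + adapter``.
    """

    sequence: str
    umi_len: int = 15
    umi_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError("adapter sequence must be non-empty")
        if not 0 <= self.umi_offset <= len(self.sequence):
            raise ValueError("umi_offset outside adapter")


#: Illumina TruSeq small-RNA 3' adapter, used as the simulator default.
DEFAULT_ADAPTER = Adapter3p("TGGAATTCTCGGGTGCCAAGG")


def _mismatches(a: str, b: str) -> int:
    # N always counts as mismatch
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _find_fixed(read: str, fixed: str, min_partial: int = 12) -> int | None:
    """Leftmost position of ``fixed`` in ``read``, allowing <= 1 mismatch per
    10 compared bases; a prefix of ``fixed`` (>= ``min_partial`` nt) may run
    off the read 3' end."""
    n, m = len(read), len(fixed)
    for p in range(n):
        overlap = min(m, n - p)
        if overlap < m and overlap < min_partial:
            break
        if _mismatches(read[p : p + overlap], fixed[:overlap]) <= overlap // 10:
            return p
    return None


def extract_umi_and_trim(
    read: ReadRecord, adapter3p: Adapter3p | str = DEFAULT_ADAPTER, umi_len: int = 15
) -> ReadRecord:
    """Locate the 3' adapter, pull out the UMI, return the trimmed insert.

    On success the returned record holds the insert bases/qualities with
    ``umi`` populated. If the adapter is not found the read is returned
    unchanged (``umi`` absent); if it is found but fewer than ``umi_len`` UMI
    bases are available the insert is trimmed but ``umi`` stays absent. Either
    way such reads end up UNASSIGNED downstream.
    """
    if isinstance(adapter3p, str):
        adapter3p = Adapter3p(adapter3p, umi_len=umi_len)
    fixed1 = adapter3p.sequence[: adapter3p.umi_offset]
    fixed2 = adapter3p.sequence[adapter3p.umi_offset :]

    if fixed1:
        p = _find_fixed(read.bases, fixed1)
        if p is None:
            return read
        umi_start = p + len(fixed1)
        insert_end = p
    else:
        q = _find_fixed(read.bases, fixed2)
        if q is None:
            return read
        umi_start = q - umi_len
        insert_end = umi_start
        if umi_start < 0:
            # adapter found flush against the read start: no room for a UMI
            return ReadRecord(read.read_id, read.bases[: max(q, 1)], read.quals[: max(q, 1)], None)

    umi = read.bases[umi_start : umi_start + umi_len]
    insert = read.bases[:insert_end]
    quals = read.quals[:insert_end]
    if not insert:
        insert, quals = read.bases[:1], read.quals[:1]  # keep record valid; UNASSIGNED later
        return ReadRecord(read.read_id, insert, quals, None)
    if len(umi) < umi_len:
        return ReadRecord(read.read_id, insert, quals, None)
    return ReadRecord(read.read_id, insert, quals, umi)


def categorize_endpoint(endpoint: int, ref: PegRNA) -> tuple[SpeciesCategory, bool]:
    """Species for a given alignment endpoint (definitional; shared with the
    simulator's truth table). Returns (category, motif_truncated)."""
    b = ref.boundaries
    if endpoint <= 0 or endpoint > len(ref):
        raise ValueError(f"endpoint {endpoint} outside reference [1, {len(ref)}]")
    pbs_start, pbs_end = b["pbs"]
    if endpoint >= len(ref):
        return SpeciesCategory.FULL_LENGTH, False
    if endpoint >= pbs_end:
        # inside the 3' motif: pegRNA core (incl. full PBS) intact
        return SpeciesCategory.FULL_LENGTH, True
    if endpoint > pbs_start:
        remaining = endpoint - pbs_start
        if remaining >= FUNCTIONAL_PBS_MIN:
            return SpeciesCategory.PBS_TRUNC_FUNCTIONAL, False
        return SpeciesCategory.PBS_TRUNC_INSUFFICIENT, False
    if endpoint > b["rtt"][0]:
        return SpeciesCategory.RTT_TRUNC, False
    return SpeciesCategory.SCAFFOLD_TRUNC, False


def classify_read(
    insert: ReadRecord, ref: PegRNA, max_mismatch_frac: float = 0.1
) -> SpeciesCall:
    """Assign one trimmed insert to a truncation species.

    The insert is aligned semi-globally against the DNA form of the reference,
    anchored at the reference 5' end with a free reference suffix (truncations
    are 3'). Endpoint ties are resolved to the longest endpoint, favoring the
    reference. Reads without a UMI, shorter than 15 nt, or below the identity
    threshold are UNASSIGNED.
    """
    if insert.umi is None or len(insert) < MIN_INSERT_LEN:
        return SpeciesCall(insert.read_id, SpeciesCategory.UNASSIGNED, umi=insert.umi)
    ref_dna = ref.sequence.replace("U", "T")
    res = edlib.align(insert.bases, ref_dna, mode="SHW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or dist / len(insert) > max_mismatch_frac:
        return SpeciesCall(insert.read_id, SpeciesCategory.UNASSIGNED, umi=insert.umi)
    endpoint = max(end for _, end in res["locations"]) + 1
    category, motif_trunc = categorize_endpoint(endpoint, ref)
    return SpeciesCall(insert.read_id, category, endpoint, insert.umi, motif_trunc)


def _directional_cluster(umi_counts: dict[str, int]) -> int:
    """Number of UMI clusters under 1-mismatch directional merging.

    A lower-count UMI b is absorbed by a neighbor a (Hamming distance 1) when
    count(a) >= 2*count(b) - 1, mirroring the directional method of common
    UMI deduplication tools.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    parent: dict[str, str] = {}
    for u in order:
        if u in parent:
            continue
        parent[u] = u
        stack = [u]
        while stack:
            cur = stack.pop()
            for v in order:
                if v in parent or v == cur:
                    continue
                if umi_counts[cur] >= 2 * umi_counts[v] - 1 and _hamming1(cur, v):
                    parent[v] = u
                    stack.append(v)
    return len({p for p in parent.values()})


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


@dataclass
class SpeciesTable:
    """UMI-deduplicated species abundances for one library.

    ``counts`` has one row per category with ``raw_reads``, ``umi_count`` and
    ``fraction`` (of assigned UMI counts; NaN throughout when the library has
    no assigned reads). ``intact_pbs_fraction`` is the UMI fraction of
    molecules whose endpoint covers the entire designed PBS — FULL_LENGTH,
    including epegRNA molecules truncated only within the 3' motif.
    """

    library_name: str
    role: str  # BULK | BOUND
    counts: pd.DataFrame
    intact_pbs_fraction: float

    @property
    def assigned_umi_total(self) -> int:
        return int(self.counts.loc[self.counts.index != "UNASSIGNED", "umi_count"].sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="category")


def dedup_and_tabulate(
    calls: Sequence[SpeciesCall],
    library_name: str,
    role: str = "BULK",
    cluster_1mm: bool = False,
) -> SpeciesTable:
    """Collapse PCR duplicates by UMI and tabulate species fractions.

    Deduplication is per (category, endpoint) bucket: exact UMI match by
    default, optional 1-mismatch directional clustering. Fractions are over
    assigned UMI counts and sum to 1 (NaN for an empty/all-unassigned
    library).
    """
    if role not in ("BULK", "BOUND"):
        raise ValueError("role must be BULK or BOUND")
    raw: dict[SpeciesCategory, int] = {c: 0 for c in SpeciesCategory}
    buckets: dict[tuple[SpeciesCategory, int | None], dict[str, int]] = {}
    intact_umi = 0
    for call in calls:
        raw[call.category] += 1
        if call.category is SpeciesCategory.UNASSIGNED:
            continue
        key = (call.category, call.endpoint)
        bucket = buckets.setdefault(key, {})
        bucket[call.umi] = bucket.get(call.umi, 0) + 1

    umi: dict[SpeciesCategory, int] = {c: 0 for c in SpeciesCategory}
    for (cat, _end), bucket in buckets.items():
        n = _directional_cluster(bucket) if cluster_1mm else len(bucket)
        umi[cat] += n
        if cat is SpeciesCategory.FULL_LENGTH:
            intact_umi += n

    assigned_total = sum(umi[c] for c in ASSIGNED_CATEGORIES)
    rows = {}
    for c in SpeciesCategory:
        frac = umi[c] / assigned_total if (assigned_total and c is not SpeciesCategory.UNASSIGNED) else float("nan")
        rows[c.value] = {"raw_reads": raw[c], "umi_count": umi[c], "fraction": frac}
    counts = pd.DataFrame.from_dict(rows, orient="index")
    intact = intact_umi / assigned_total if assigned_total else float("nan")
    return SpeciesTable(library_name, role, counts, intact)


def compare_bound_vs_bulk(bound: SpeciesTable, bulk: SpeciesTable) -> pd.DataFrame:
    """Per-category enrichment of effector-bound over bulk species.

    Returns one row per assigned category with bound/bulk UMI fractions, their
    ratio (inf, with a warning, when the bulk fraction is zero), a
    two-proportion z-test p-value on the UMI counts, and an ``enriched`` flag
    for ratio > 1.
    """
    nb = bound.assigned_umi_total
    nk = bulk.assigned_umi_total
    rows = []
    for c in ASSIGNED_CATEGORIES:
        fb = bound.counts.loc[c.value, "fraction"]
        fk = bulk.counts.loc[c.value, "fraction"]
        cb = int(bound.counts.loc[c.value, "umi_count"])
        ck = int(bulk.counts.loc[c.value, "umi_count"])
        if fk == 0:
            if fb > 0:
                warnings.warn(
                    f"{c.value}: bulk fraction is zero; ratio reported as inf",
                    stacklevel=2,
                )
                ratio = float("inf")
            else:
                ratio = float("nan")
        else:
            ratio = fb / fk
        if nb and nk and (cb + ck) and (cb + ck) < nb + nk:
            _, pval = proportions_ztest([cb, ck], [nb, nk])
        else:
            pval = float("nan")
        rows.append(
            {
                "category": c.value,
                "bound_fraction": fb,
                "bulk_fraction": fk,
                "ratio": ratio,
                "p_value": pval,
                "enriched": ratio > 1 if ratio == ratio else False,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def profile_library(
    reads: Iterable[ReadRecord],
    ref: PegRNA,
    adapter3p: Adapter3p | str = DEFAULT_ADAPTER,
    library_name: str = "library",
    role: str = "BULK",
    max_mismatch_frac: float = 0.1,
    cluster_1mm: bool = False,
) -> SpeciesTable:
    """End-to-end: UMI extraction -> classification -> UMI-deduplicated table."""
    calls = [
        classify_read(extract_umi_and_trim(r, adapter3p), ref, max_mismatch_frac)
        for r in reads
    ]
    return dedup_and_tabulate(calls, library_name, role, cluster_1mm)
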