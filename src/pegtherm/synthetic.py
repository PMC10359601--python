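"""Seeded generators for toy loci and truncated small-RNA-seq read sets.

Every stage of the pipeline can be exercised without downloads: toy target
loci with controlled PBS-source GC content, loci constructed so a chosen PBS
length is the unique Tm-optimal design, and FASTQ read sets drawn from a
specified 3'-truncation endpoint distribution with known per-read truth
(category + UMI). The same seed always reproduces byte-identical output.

The truncation model emulates the structure of U6-expressed pegRNA pools —
a dominant full-length species plus a 3'-truncation ladder — not the
biochemistry that produces it: no ligation bias, no PCR-duplication family
size distribution (duplicates are injected at a flat rate), substitution
errors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pegrna import PegRNA, TargetLocus
from .seq_io import NucleicSeq, ReadRecord
from .thermo import ThermoParams, tm_nearest_neighbor
from .truncation import DEFAULT_ADAPTER, Adapter3p, categorize_endpoint

__all__ = [
    "SimConfig",
    "make_toy_locus",
    "simulate_reads",
    "make_tm_planted_locus",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Read-set simulation parameters; the seed fully determines the output.

    The 3'-truncation model is either ``p_full`` + a geometric tail over the
    truncation length (default decay 0.1 per nt), or an explicit
    ``endpoint_hist`` mapping endpoint -> probability (must sum to 1).
    ``duplicate_rate`` is the probability that a molecule is read twice
    (same UMI and insert), emulating PCR duplication.
    """

    seed: int
    n_reads: int
    p_full: float = 0.7
    tail_geom_p: float = 0.1
    endpoint_hist: dict[int, float] | None = None
    error_rate: float = 0.0
    duplicate_rate: float = 0.0
    umi_len: int = 15
    adapter: Adapter3p = DEFAULT_ADAPTER
    qual: int = 30

    def __post_init__(self) -> None:
        for name in ("p_full", "tail_geom_p", "error_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.endpoint_hist is not None:
            total = sum(self.endpoint_hist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"endpoint_hist probabilities sum to {total}, not 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_toy_locus(gc_frac: float, seed: int, flank: int = 40) -> TargetLocus:
    """Random locus whose 17-nt PBS-source region has the requested GC fraction.

    The PBS-source region is protospacer positions 1-17 (the bases whose
    reverse complement forms every candidate PBS); its GC count is
    ``round(gc_frac * 17)``, within 0.05 of the request. Deterministic per
    seed.
    """
    if not 0.0 <= gc_frac <= 1.0:
        raise ValueError("gc_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_gc = round(gc_frac * 17)
    src = np.empty(17, dtype="<U1")
    gc_pos = rng.choice(17, size=n_gc, replace=False)
    mask = np.zeros(17, dtype=bool)
    mask[gc_pos] = True
    if n_gc:
        src[mask] = rng.choice(list("GC"), size=n_gc)
    if 17 - n_gc:
        src[~mask] = rng.choice(list("AT"), size=17 - n_gc)
    protospacer = "".join(src) + _random_seq(rng, 3)
    pam = str(rng.choice(_BASES)) + "GG"
    window = _random_seq(rng, flank) + protospacer + pam + _random_seq(rng, flank)
    return TargetLocus(
        window=NucleicSeq(window, "DNA", f"toy_gc{gc_frac:.2f}_s{seed}"),
        protospacer_start=flank,
        strand="+",
    )


def _sample_endpoint(rng: np.random.Generator, cfg: SimConfig, ref_len: int) -> int:
    if cfg.endpoint_hist is not None:
        eps = sorted(cfg.endpoint_hist)
        probs = np.array([cfg.endpoint_hist[e] for e in eps])
        return int(rng.choice(eps, p=probs / probs.sum()))
    if rng.random() < cfg.p_full:
        return ref_len
    trunc = int(rng.geometric(cfg.tail_geom_p))
    return max(1, ref_len - trunc)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("<U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


def simulate_reads(ref: PegRNA, cfg: SimConfig) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a small-RNA-seq library of 3'-truncated pegRNA molecules.

    Each read is a reference prefix up to a sampled endpoint (substitution
    errors applied to the insert), followed by the 15-base UMI and the fixed
    3' adapter. Returns the reads plus a truth table recording every read's
    endpoint, true species category and UMI.
    """
    rng = np.random.default_rng(cfg.seed)
    ref_dna = ref.sequence.replace("U", "T")
    fixed1 = cfg.adapter.sequence[: cfg.adapter.umi_offset]
    fixed2 = cfg.adapter.sequence[cfg.adapter.umi_offset :]

    reads: list[ReadRecord] = []
    truth_rows = []
    i = 0
    while len(reads) < cfg.n_reads:
        i += 1
        endpoint = _sample_endpoint(rng, cfg, len(ref_dna))
        umi = _random_seq(rng, cfg.umi_len)
        insert = _apply_errors(rng, ref_dna[:endpoint], cfg.error_rate)
        bases = insert + fixed1 + umi + fixed2
        category, motif_trunc = categorize_endpoint(endpoint, ref)
        n_copies = 1
        if cfg.duplicate_rate > 0.0 and rng.random() < cfg.duplicate_rate:
            n_copies = 2
        for c in range(n_copies):
            if len(reads) >= cfg.n_reads:
                break
            rid = f"sim{cfg.seed}_{i:07d}" + ("" if c == 0 else f"_dup{c}")
            reads.append(ReadRecord(rid, bases, [cfg.qual] * len(bases)))
            truth_rows.append(
                {
                    "read_id": rid,
                    "endpoint": endpoint,
                    "category": category.value,
                    "motif_truncated": motif_trunc,
                    "umi": umi,
                    "is_duplicate": c > 0,
                }
            )
    return reads, pd.DataFrame(truth_rows)


def make_tm_planted_locus(
    L_star: int,
    t_target: float,
    seed: int,
    params: ThermoParams | None = None,
    l_range: tuple[int, int] = (4, 17),
    tm_window: float = 0.5,
    margin: float = 2.0,
    max_tries: int = 50_000,
) -> TargetLocus:
    """Rejection-sample a locus whose unique Tm-optimal PBS length is ``L_star``.

    Accepts a locus when Tm(PBS of length L_star) is within ``tm_window`` °C of
    ``t_target`` and every other length in ``l_range`` differs from
    ``t_target`` by more than ``margin`` °C, so the optimum is planted
    unambiguously. Deterministic per seed; raises when the sampling budget is
    exhausted (suggesting looser margins).
    """
    from .pegrna import derive_pbs  # local import to avoid cycle at module load

    if not l_range[0] <= L_star <= l_range[1]:
        raise ValueError(f"L_star {L_star} outside l_range {l_range}")
    if params is None:
        params = ThermoParams()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        gc = float(rng.uniform(0.0, 1.0))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        locus = make_toy_locus(gc, sub_seed)
        ok = True
        for L in range(l_range[0], l_range[1] + 1):
            tm = tm_nearest_neighbor(derive_pbs(locus, L), params).tm_celsius
            d = abs(tm - t_target)
            if L == L_star:
                if d > tm_window:
                    ok = False
                    break
            elif d <= margin:
                ok = False
                break
        if ok:
            return locus
    raise RuntimeError(
        f"no locus with planted L*={L_star} at {t_target}°C found in {max_tries} "
        f"tries; loosen tm_window/margin"
    )
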