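# Methods

## Scope and model

`pegtherm` implements the computational core of temperature-matched pegRNA
design for prime editing with SpCas9-H840A (spacer fixed at 20 nt, nick
between protospacer positions 17/18 on the non-target strand; other effectors
are out of scope) plus UMI-based 3′-truncation profiling of pegRNA pools.
Edit positions use the nick-relative convention throughout: +1 is the first
nucleotide 3′ of the nick on the non-target strand, so +1..+3 are protospacer
positions 18–20 and +4..+6 the PAM. Internally all coordinates are 0-based
half-open; user-facing reports are 1-based inclusive.

## Nearest-neighbor thermodynamics

The Tm engine treats the duplex as fully Watson–Crick paired — exactly the
geometry of a PBS derived from its own protospacer — and computes

    Tm(K) = 1000·ΔH / (ΔS′ + R·ln(C_T/4)),   R = 1.987 cal mol⁻¹ K⁻¹

from initiation-plus-stack sums keyed on the probe strand 5′→3′. Parameter
sets (versioned in `data/nn_tables.json`): Sugimoto et al. 1995 for RNA:DNA
hybrids (keyed on the RNA strand; a DNA probe is accepted and keyed on its
implied RNA complement), SantaLucia–Hicks 2004 unified for DNA:DNA (with
per-end A/T terminal penalties), Xia et al. 1998 for RNA:RNA (initiation plus
terminal-AU penalties). Symmetric chemistries store all 16 stack keys with
mirrored values so every table is complete.

Defaults, chosen once and frozen: Na⁺ = 150 mM (physiological monovalent),
C_T = 10⁻⁴ M (RNP-assembly-scale strand concentration), SantaLucia-1998
entropy salt correction (ΔS′ = ΔS + 0.368·(N−1)·ln[Na⁺]); Schildkraut and
no-correction variants are selectable. The C_T/4 factor is used throughout
because PBS and target are distinct, non-self-complementary strands. These
are this package's calibration choices — the defaults are recorded in every
`TmResult` and are not presented as anyone else's settings. ΔG37 is reported
at the tabulated 1 M reference state (no salt correction), consistent with
how the underlying parameter sets are published.

The engine is validated against an independent nearest-neighbor
implementation (Biopython's `MeltingTemp`, same published parameter sets):
agreement is at machine precision, asserted at 0.5 °C over random panels.
Known property: Tm is *mostly* non-decreasing when a duplex is extended —
about 5% of random single-base extensions lower Tm slightly (≤ ~3 °C),
almost always when Tm is already far above the design-relevant range,
because a weak appended stack dilutes the duplex's mean stability. Below 4 nt
the model is unreliable and the engine refuses to run.

The Wallace rule (4 °C per G/C, 2 °C per A/T or U) is provided as the
base-composition alternative; it carries no ΔH/ΔS and is not used for
ranking.

## PBS/RTT derivation and assembly

PBS(L) is the RNA reverse complement of protospacer positions 18−L..17, so
it anneals the last L nt of the nicked non-target strand with zero
mismatches. The family is nested at the 5′ side: PBS(L) = PBS(L+1)[:L]
(lengthening appends bases at the PBS 3′ terminus, which is the pegRNA 3′
end). The RTT is the RNA reverse complement of the *edited* non-target
strand from the nick through the edit end plus a homology arm, so its 3′
terminus abuts the PBS and templates +1 first; reverse-transcribing it
(complement + reverse) reproduces the intended edited sequence exactly,
which is a tested round-trip invariant. The shipped scaffold is the
canonical S. pyogenes constant; alternate scaffolds and a 3′ motif (e.g. the
tevopreQ1 pseudoknot for epegRNAs) are injectable. A 5′-G spacer requirement
is not enforced — synthetic/RNP pegRNAs have no such constraint — but a
warning is emitted in expression-plasmid mode.

## Auto-inhibition scoring

`pbs_pairs` counts contiguous Watson–Crick pairs anchored at spacer position
17 walking 5′ (strict pairing, no G·U wobble — the score models the
competition between perfect self-pairing and perfect target pairing, and
wobble would affect both asymmetrically in ways the NN tables here do not
parameterize). "First 3 nt of the RTT" is interpreted as the three RTT
nucleotides immediately 5′ of the PBS — those templating +1..+3 — since only
they can pair spacer positions 18–20; the extension counts only pairs
contiguous with the PBS duplex, because duplex propagation is the physical
mechanism (an edit at +1 zeroes the extension even if +2/+3 match). The
fold-back ΔG37 uses the RNA:RNA table on the spacer-side strand of the
paired region. The severity flag defaults to a ≥10 bp duplex (lengths that
abolish target cleavage in vitro, vs partial inhibition at 7–8 bp) and is
configurable; no validated quantitative inhibition→efficiency map exists, so
the report exposes raw numbers rather than a predictor.

The rescue oligo is the exact DNA complement of the PBS (or RTT+PBS, the
default — an oligo covering the PBS alone leaves the RTT/spacer homology
free to pair) and is emitted 5′→3′.

## PBS-length optimization

Objective: two-sided |Tm − T_target| — the design temperature should be
*matched*, not merely reached — with ties broken toward the shorter PBS.
Default range 4–17 nt: 4 is the NN-validity floor, 17 the longest length in
routine use at A/T-rich sites. Presets: 37.0 (mammalian culture), 28.5
(zebrafish embryos), 30.0 °C (cold shock; the report notes that shorter PBS
lengths are tolerated or preferred at 30 °C — no separate scoring model is
invented). The full ranked list is always returned. For unprotected,
plasmid-expressed pegRNAs (subject to 3′ truncation) the empirically optimal
PBS is longer (~13 nt at balanced GC); the optimizer targets end-protected
pegRNAs and surfaces the plasmid case as an informational note only.

Stoichiometry scales linearly from validated anchors: RNP electroporation
50 pmol PE : 200 pmol pegRNA : 15–30 pmol nicking sgRNA (pegRNA:PE = 4:1),
fibroblast/T-cell 150:600:45 pmol, embryo injection 6 µM PE : 12 µM pegRNA :
nicking = pegRNA/10 (note the embryo anchor is 2:1 pegRNA:PE, not 4:1), mRNA
1 µg : 100 pmol : 50 pmol. The nicking guide is always sub-stoichiometric to
the pegRNA because in excess it displaces the pegRNA from the limited
effector protein.

## Truncation profiling

Adapter/UMI handling: the 3′ ligation adapter is modeled as
`fixed[:umi_offset] + UMI(15) + fixed[umi_offset:]` with the UMI first by
default; the fixed part is located allowing ≤1 mismatch per 10 compared
bases (N always mismatches), leftmost match wins, and a ≥12-nt adapter
prefix at the read 3′ end is accepted. Reads whose adapter is missing, or
found without room for a complete UMI, are retained and become UNASSIGNED.

Classification aligns the insert semi-globally against the DNA form of the
designed pegRNA, anchored at the reference 5′ end with a free reference
suffix (truncations are strictly 3′), unit mismatch/gap costs via edlib;
endpoint ties resolve to the longest endpoint (truncation, not internal
variation, is the signal). Identity threshold 90% of insert length; inserts
<15 nt are UNASSIGNED. Category by the region containing the last aligned
base: full reference → FULL_LENGTH; within the PBS leaving ≥7 nt →
PBS_TRUNC_FUNCTIONAL, 1–6 nt → PBS_TRUNC_INSUFFICIENT (the 7-nt
functionality cutoff is a parameter); endpoint at the RTT/PBS border leaves
0 PBS nt and is an RTT truncation; within scaffold or spacer →
SCAFFOLD_TRUNC. Five named species plus UNASSIGNED partition every read; for
epegRNA references, endpoints inside the 3′ motif are reported as
FULL_LENGTH of the pegRNA core with a motif-truncation sub-flag, so no
information is lost. "Intact PBS" = UMI fraction of molecules whose endpoint
covers the entire designed PBS (FULL_LENGTH, including motif-only
truncations).

Molecule counting deduplicates UMIs within each (category, endpoint) bucket:
exact match by default, optional 1-mismatch directional clustering (a
lower-count UMI is absorbed by a Hamming-1 neighbor when the neighbor's
count ≥ 2×count−1). Bound-vs-bulk comparison reports per-category fraction
ratios with a two-proportion z-test on UMI counts; a zero bulk fraction
yields an infinite ratio with a warning.

The classifier is verified against an exhaustive endpoint-scan oracle (every
reference prefix scored with end-gap + mismatch costs, ties to the longest
endpoint): 100% category agreement on error-free reads.

## Synthetic data

The generators provide controlled ground truth, not realism. Toy loci place
a random NGG protospacer with an exact GC count in the 17-nt PBS-source
region (positions 1–17) and 40-nt flanks. Planted-optimum loci
rejection-sample until one PBS length is uniquely Tm-optimal (within 0.5 °C
of target; all others >2 °C away). Read simulation draws an endpoint per
molecule — either `p_full` plus a geometric truncation tail (default decay
0.1/nt; no empirical truncation-length distribution is established, and the
generator's role is controlled truth) or an explicit endpoint histogram —
then emits reference-prefix + UMI + adapter reads with substitution errors
on the insert (constant Q30 qualities; indels are negligible at small-RNA
scale and are not modeled), optional flat-rate PCR duplication (same UMI and
insert), and a truth table of every read's endpoint, category and UMI. The
same configuration is byte-identical per seed. Not emulated: ligation bias,
PCR family-size distributions, UMI errors, RNA modifications — so passing
tests demonstrate correctness of the analysis on reads matching these
assumptions, not performance on any particular wet-lab library.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` run entirely on synthetic inputs:
50-sequence panels for cross-engine Tm agreement (asserted at 0.5 °C;
observed at machine precision), 100 planted loci for optimizer recovery
(100/100 expected by construction — the planting procedure guarantees a
unique argmin), 1,000 error-free reads for classifier/oracle agreement,
20,000-read libraries for planted-fraction recovery (3 binomial SE), and
10,000-read pairs for the 2× bound-vs-bulk enrichment. Temperature-matched
worked examples use planted stand-in loci generated by the package itself,
labelled synthetic; they exercise the full design path with a known answer.

## Known limitations

No Mg²⁺/dNTP corrections, mismatch or dangling-end thermodynamics, or
secondary-structure partition functions; the auto-inhibition score is a
duplex-length/ΔG report, not a validated efficiency predictor; no RTT-length
optimization, PAM scanning, nicking-guide discovery or off-target scoring;
the profiler does not model library-prep bias and is not a genome aligner.
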