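# Methods

This note documents the models behind each stage of the pipeline, the
parameters that matter, the design decisions taken where conventions vary,
and what the synthetic data do and do not establish about real data.

## Motif screening

Coordinates are 0-based and half-open everywhere; a *spacer* counts the
residues strictly between two motif spans. The screen keeps a sequence iff
it is at least `min_length` residues (default 365), contains at least one
CXXCH, and contains the upstream motif ending at or before the first
CXXCH. The operational upstream pattern is the Methods-style
P-X-F-A-R-[Q/K]-[T/Y]; the fuller consensus A-X-P-X-F-A-R-[Q/K]-[T/Y] is a
description of the family logo, not a filter, and the screen does not
require it. Annotation anchors on the first (N-terminal-most) CXXCH,
matching the monoheme N-terminal cytochrome domain; the upstream motif is
the *rightmost* qualifying match, the downstream PXL the *first* match
after the CXXCH.

Ambiguity handling is conservative: an `X` in a sequence satisfies
wildcard positions of a motif but never a literal position; B/Z/U never
match motif literals. Canonical spacer values (5 upstream, 4 downstream)
are *not* enforced by default — `ScreenRules(enforce_spacers=True)` turns
non-canonical spacing into a named rule failure, and the expected values
are configurable because the literature convention for counting "n
residues upstream" (inclusive vs exclusive) is not fixed.

Dereplication is greedy longest-first in the cd-hit style: a sequence is
dropped when a retained, longer-or-equal sequence aligns to it with
identity ≥ 100% over ≥ 90% of the shorter sequence. Identity here is
computed over both-aligned columns and coverage is those columns over the
shorter length — deliberately different from whole-alignment AAI, which
would never reach 1.0 for a perfect fragment. Equal-length ties retain the
lexicographically smaller id so the result is order-independent.

## Alignment, masking, AAI, logos

Pairwise alignment is affine-gap global Needleman–Wunsch over BLOSUM62
with gap open 11 / extend 1 (a gap of length L costs 11 + (L−1)·1),
delegated to Biopython's `PairwiseAligner`. Letters outside the matrix
alphabet (U) are scored through the matrix wildcard row; the aligned
strings keep the original letters. Because co-optimal alignments exist,
the pair is aligned in a canonical order internally so score and identity
are symmetric in the arguments.

The multiple aligner is progressive: fractional 3-mer distances →
UPGMA guide tree (scipy average linkage) → profile–profile merging, where
a column pair scores the expectation of BLOSUM62 over the two columns'
residue frequencies (gap mass contributes zero) and the same affine
penalties apply. This is a deliberately simple, fully reproducible
aligner: it preserves the degapped sequences exactly and is adequate for
the highly similar within-cluster families it is used on, but it is not a
replacement for a production aligner on divergent sequences.

Masking removes alignment columns whose gap fraction strictly exceeds 30%
(a column at exactly 30% stays). The denominator is the number of rows and
terminal gaps count as gaps, matching standard masking tools. AAI is
computed from fresh pairwise alignments *before* masking, as matches over
all alignment columns; a mode that extracts pairs from an existing MSA
(dropping the pair's dual-gap columns) is provided because both
conventions occur in practice.

Logo information content is log₂20 − H per column, entropy taken over the
non-gap residue frequencies. The consensus renders `[A/B]` when the top
two frequencies both reach 0.35, `X` when the modal frequency is below
0.5, and `-` for all-gap columns; frequency ties order alphabetically.
The small-sample entropy correction is off by default — the logos this is
meant for are built from hundreds of sequences — but can be enabled.

## Profile models and classification

Full profile-HMM machinery is reduced to a match/insert/delete Viterbi
profile with fixed per-model gap penalties: match states are columns with
≤ 50% gaps (a standard construction convention), emissions are
pseudocount-1 smoothed frequencies turned into log-odds (bits) against the
pooled match-column background, and insert/delete penalties derive from
the observed gap-opening/extension frequencies clipped into [2, 10] and
[0.5, 4] bits. Scoring is glocal — the model must be traversed end to
end, unaligned sequence flanks are free — so a score never depends on
residues outside the matched window. Transition probabilities are not
re-estimated (no Baum–Welch): the decision structure, not the exact bit
values of any external tool, is the point, and scores are deterministic to
the bit.

The "optimum bit score cutoff" — a human visual judgment in practice — is
operationalized deterministically: when positive and negative score
distributions separate, the cutoff is the midpoint of the gap; otherwise
the threshold maximizing F1, ties toward the higher (stricter) cutoff.
Classification applies guards in a fixed order (no CXXCH → excluded; < 365
residues → excluded) before scoring, then assigns the best cluster among
profiles whose cutoff is met. An excluded record never carries a cluster
call.

## Redox potentiometry

Fraction estimation: the fully-oxidized and fully-reduced absorbances at
each monitored wavelength are plateau *medians* over the first and last
`endpoint_window` (default 5) readings — robust to single-reading noise;
the endpoint convention is otherwise unspecified in the assay tradition.
A channel whose plateau difference is within 10× the endpoint standard
deviation raises an error rather than producing garbage fractions, and the
dye channel must decrease (oxidized DCPIP is the absorbing species at
610 nm). The heme ratio is f/(1−f) at 429 nm; the dye ratio likewise from
the falling 610 nm signal.

The Nernst slopes are fixed at 25 and 12.5 mV per natural-log unit —
RT/nF at room temperature as the assay arithmetic rounds it — rather than
computed from a temperature parameter, so the transform reproduces the
standard calculation exactly. The exclusion window keeps ratios in
[0.065, 10]; both bounds are inclusive (exclusion is *strictly* greater
than 10 or less than 0.065) and the window is intentionally asymmetric on
the log scale (0.065 ≠ 1/10) — it is applied as given. The line fit is
ordinary least squares with a free slope; the slope is a quality-control
output (unit slope indicates both couples obey their assigned electron
counts) and is not constrained to 1. The midpoint is E_dye + intercept;
replicates aggregate as mean ± sample SD (ddof = 1). An optional 2×2
linear unmixing hook corrects heme/dye spectral cross-talk; it is off by
default because the two monitored bands are treated as spectrally
independent.

Peak finding smooths with a 3-point moving average and reports the highest
local maximum in the window, ties to the lowest wavelength; monotone or
flat windows raise an error.

## Fe(II)–citrate speciation

The solver works at fixed pH (the buffer is assumed non-complexing and is
not modeled), with unit activity coefficients — appropriate to the ~20%
precision of the question being asked — and Newton iteration on the log
free-component concentrations, converging each mass balance to 1e-12
relative with a deterministic start from the totals and a ±2 log-unit step
cap for robustness.

The default reaction table is the minimal set that describes the assay:
FeCit⁻ formation plus the three citrate protonation steps
(log K = 6.40, cumulative 11.16 and 14.29). Constants are configuration,
not code, and are the NIST SRD 46 critically selected values at 25 °C and
infinite dilution — the same reference state MINTEQ-style programs use.
One subtlety deserves emphasis: the Fe(II)–citrate constant commonly
quoted as log K = 3.20 is the 0.1 M ionic-strength value; the
infinite-dilution value is 4.38. At 2 mM Fe(II) / 2 mM citrate / pH 6.3
the minimal system gives a free-Fe²⁺ fraction of 0.56 with 3.20 but 0.196
with 4.38, and only the latter matches MINTEQ-style speciation of this
assay (~20% free Fe²⁺). The default therefore uses 4.38; the sensitivity
table written by `analysis/06_fe_speciation.py` makes the dependence
explicit, and any constant set can be supplied as JSON.

## Synthetic data: what it emulates and what it does not

**Families.** Each cluster has one ancestor (deterministic in seed and
cluster label): a 21-residue signal peptide, a 90-residue cytochrome
region containing the motif skeleton (upstream motif, 5-residue spacer,
CXXCH, 4-residue spacer, PXL) at a fixed offset, and a random porin tail
to the configured length (450 by default, emulating the observation that
confirmed homologs are mostly ≥ 400 residues). Members substitute per
site at 5% in the cytochrome region and 40% in the porin region,
reproducing the conserved-cytochrome / variable-porin contrast; motif
sites are frozen (the [Q/K] and [T/Y] bracket positions still sample both
letters, so family logos show the two-way split). Spacer residues exclude
P and L so no accidental flanking-motif match can shift the measured
spacers; accidental CXXCH windows are scrubbed everywhere, so every member
carries exactly one. Decoy classes ablate exactly one property each:
CXXCH removed, truncation to 300 residues, or upstream motif removed.

Mutations are substitutions only — no indels, no rate heterogeneity, no
phylogenetic structure within a family — so passing tests show the
pipeline's rules and decision structure are correct, not that the aligner
or profiles would meet any particular accuracy on real, indel-rich,
unevenly sampled homolog sets. Cluster separation in this simulation is
deliberately easy (independent porin ancestors); real cluster boundaries
are harder.

**Titrations.** Enzyme kinetics are abstracted to a constant electron
delivery rate (0.05 µM e⁻/s) acting on 5 µM of a one-electron heme couple
(midpoint 208 mV by default, so the round trip exercises the regime of
interest) and 30 µM of a two-electron dye couple (217 mV). Delivery
starts after a 120 s lag, emulating the baseline readings collected before
the reaction is initiated; without such a lag the heme is already
partially reduced at the first reading (its couple titrates earlier than
the dye's at these midpoints) and the fully-oxidized plateau cannot be
estimated from the trace at all. At each 15 s time step the solution
potential is found by bisection from the two-couple electron balance;
absorbances are state-weighted plateau values (or full band-model spectra:
oxidized Soret 410 nm; reduced Soret 427 nm, β 530 nm, α 560 nm; oxidized
dye 610 nm) plus Gaussian noise (0.001 AU default). Plateau heights are
free parameters chosen for numerical conditioning, not measured extinction
coefficients. The model omits instrument drift, baseline shifts, enzyme
slowdown and dye–heme spectral overlap, so recovery accuracy on real
traces will be limited by those effects, not by the arithmetic verified
here.

## Problem sizes

The analysis scripts and tests use 20-member training families, 50-member
holdout sets per cluster, 50-member decoy draws, 4 replicate titrations of
241 readings, and 100-MSA masking comparisons — sizes chosen so every
stage's behavior is exercised with comfortable statistical margins while
the whole pipeline remains quick to run on a laptop.

## Known limitations

* The progressive aligner has no iterative refinement; column quality on
  divergent real families will trail dedicated aligners.
* Profile bit scores are internally consistent but not comparable to any
  external tool's bit scores; only the decision structure (guards, argmax,
  thresholding) is portable.
* The speciation solver handles soluble complexes at fixed pH only — no
  solids, gases, redox couples or ionic-strength corrections.
* Tree building and bootstrap support are out of scope; cluster truth in
  the simulations substitutes for phylogenetic placement.
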