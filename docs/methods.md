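# Methods

This note documents the statistical models behind `seriamap`, the
defaults and why they were chosen, the approximations made, and what
the bundled simulator does and does not emulate.

## Population models

All supported crosses descend from two parents. Hidden state spaces
per individual and locus:

| design | hidden states | transition between adjacent loci |
|---|---|---|
| BC, DH | 2 (transmitted F1 gamete allele) | swap w.p. r |
| F2 | 4 = (maternal allele) × (paternal allele) | Kronecker of two 2-state chains, same r |
| RIL*n*, IRIL*t* | 2 (fixed-line genotype) | swap w.p. R(r), see below |
| CP | 4 = (homolog from parent 1) × (homolog from parent 2) | Kronecker of two 2-state chains |

**RIL/IRIL transform.** A recombination fraction r per meiosis
accumulates over the generations of inbreeding into a larger
observed-line recombination fraction R. For selfing to fixation
R = 2r/(1+2r) (Haldane–Waddington). For finite selfing generations and
for IRILs (t generations of random intermating between the F2 and the
selfing phase) R is computed by iterating the exact 16-state two-locus
diploid genotype chain from the F1 and conditioning on double
homozygosity; a monotone PCHIP interpolant of that curve (grid step
1e-3 in r) provides the fast vectorized forward/inverse maps used
inside EM loops (max interpolation error far below the 5e-4 tolerance
asserted against grid-search ML). Residual heterozygosity of finite-n
RILs enters the emission, not the state space: an exact
multi-generation multilocus chain would be disproportionate to the
accuracy it buys.

## Two-point estimation

Every design reduces to the shared coefficient form
P(obs | r) ∝ Σₘ N[obs, m] rᵐ(1−r)^(M−m) (see the module docstring of
`seriamap.models`). EM over r has the closed-form M-step
r ← E[recombinant meioses]/(M · n) and is vectorized across all pairs
that share a coefficient table, which makes the full pairwise matrix
of a few hundred markers a sub-second operation. For CP pairs the
likelihood is maximized over the ≤ 4 relative parental phase
configurations; the LOD baseline at r = 0.5 is phase-invariant, so
phases are ranked by their LOD directly. Pairs whose observation
classes carry no linkage information (all coefficient rows binomial in
m — e.g. a female-only with a male-only pseudo-testcross marker)
report `informative = False` and LOD 0.

Numerical choices: r clamped to [1e-6, 0.5]; convergence when the
log-likelihood changes by < 1e-8 (relative), at most 200 iterations;
r initialized at 0.25; LOD floored at 0. F2 dominant codes (C = "not
A", D = "not B") contribute through compatible-state marginalization.
For RIL/IRIL the two-point likelihood is computed on observed line
classes (the R scale) and the reported r is the inverse transform;
heterozygous RIL calls are treated as uninformative at the two-point
stage (they carry almost no pairwise linkage information) while the
multipoint emission does use them.

## Multipoint engine

Forward–backward with per-locus scaling (likelihoods are accumulated
in log10); missing observations emit 1 in every state, which is
exactly the EM treatment of missing data. Baum–Welch refits interval
recombination fractions from expected chain-switch counts (the
Kronecker structure makes the per-interval expected number of
recombinant gametes a posterior-weighted Hamming distance); for
RIL/IRIL the update lives on the R scale and is pulled back through
the transform. EM stops when Δlog10 L < 1e-6 or after 100 iterations.

**Emission error model.** Observed codes equal the code implied by the
hidden state with probability 1 − ε, otherwise one of the other valid
codes uniformly. ε defaults to 0.01 as a starting value and is then
*estimated* by an EM outer loop (expected fraction of posterior-
incompatible calls), clamped to [1e-4, 0.2]. Estimating ε matters in
both directions: a fixed ε > 0 on clean data absorbs genuine double
crossovers and deflates the map by several percent, while a fixed
small ε under-corrects noisy data. The estimate is refreshed on the
dense framework at the end of densification because a sparse scaffold
overestimates ε (double crossovers inside wide intervals are
indistinguishable from miscalls there).

**Insertion scans.** Scaffold elongation, densification, placement and
robustness checks all need "what does the likelihood become if marker
x is inserted at position p". With cached forward/backward factors
this is an O(n·S²) contraction per position: the candidate is scored
at every interval (relative position probed on a fixed grid, then
refined by bounded scalar optimization) and beyond both ends (distance
grid up to 35 cM, refined likewise), holding the other intervals
fixed. Distances are re-fitted by full EM after every acceptance, so
the fixed-interval approximation only affects candidate *ranking*,
and a final verification pass (below) guards the delivered map.

**CP phases.** Phases are two bits per marker (which parental allele
sits on homolog 1; −1 for a homozygous parent). The first scaffold
marker anchors the labeling; every extension or insertion evaluates
the candidate's ≤ 4 phase configurations and keeps the argmax — the
on-the-fly maximum-likelihood phasing. Note one genuine
non-identifiability: a chain consisting solely of ab×ab markers in
parent-symmetric phases cannot distinguish the two parents (swapping
them is an exact likelihood symmetry); any marker class that treats
the parents asymmetrically breaks it, so realistic mixed-class data
are identifiable.

## Ordering

1. **Seeds.** Markers are partitioned into linkage neighborhoods as
   connected components of the LOD ≥ 10 graph (stringent on purpose: a
   dataset of a few hundred markers contains tens of thousands of
   unlinked pairs and a handful reach LOD 3–6 by chance, which would
   fuse chromosomes; genuinely adjacent markers sit far above 10).
   One seed pair per component (or per anchor-map chromosome):
   highest-LOD pair with r̂ in the scaffold window — a pair too tight
   (r̂ < 0.05) cannot orient the seriation, since moving a candidate
   across it costs almost no likelihood.
2. **Scaffold.** Bidirectional elongation: the highest-LOD candidate
   within r̂ ∈ [0.05, 0.25] of a terminal marker is appended iff its
   maximum-likelihood position is that end *and* the insertion-scan
   LOD gap stays ≥ the threshold. The window keeps the scaffold
   sparse (hence highly robust) yet able to reach chromosome ends.
   Scaffolds that end up strongly linked (LOD ≥ 10) are concatenated
   at their closest terminals, with CP phases re-harmonized by ML.
3. **Framework.** Candidates in decreasing informativeness
   (non-missing count, then best LOD to the group, then name) are
   inserted at their ML position and kept iff the gap between best
   and second-best position is ≥ the order-robustness LOD (default
   3.0). Error detection runs every 30 acceptances.
4. **Verification and pruning.** `verify_order_robustness` re-scores
   every marker by exhaustive single-marker repositioning (the marker
   is removed, the chain re-factored, and all positions re-scanned)
   plus adjacent-pair flips re-fitted by EM; groups of ≤ 7 loci are
   scored exactly with per-order EM refits. The statistic is a
   documented approximation of the all-orders minimum LOD — full
   order enumeration is combinatorially out of reach, and single
   moves + flips are in practice where the nearest competing orders
   live. Because the insertion-time gap is computed against an
   evolving map, a few accepted markers can end below the gate in the
   final context; the framework is therefore pruned until it passes
   its own verification, demoting one marker per run of consecutive
   weak loci per pass and preferring interior markers so that
   chromosome-end coverage survives while local density gives way.
   Scaffold membership grants no immunity: delivered-framework
   robustness outranks seriation history.

Tie-breaks everywhere are lexicographic in marker name; the pipeline
contains no hidden randomness, so a fixed input and parameter set
reproduces the map bitwise.

## Assignment and placement

Markers join the linkage group holding their best 2-point LOD partner,
subject to LOD ≥ 6 and a ≥ 3 gap over the runner-up group (both
config-exposed); markers failing the first are `unlinked`, the second
`ambiguous`, and neither is placed. Placement scans each leftover
marker against the frozen framework and records the ML bin and
within-bin position; framework coordinates are untouched by
construction. A marker whose ML position falls before the first
framework marker is truncated to position 0 (end bins are half-open;
the group origin is part of the frozen skeleton), while markers beyond
the last framework marker extend the total map. Twins re-attach at
their representative's position; the order of multiple markers placed
in one bin (by within-bin position, ties by name) carries no
statistical support — the bin is the resolution limit.

## Error handling

Two detectors, both masking flagged calls to missing (never rewriting
them to imputed values, so a wrong flag costs one observation, not a
fabricated one):

- **Posterior method** — a call is flagged when the posterior mass on
  hidden states compatible with it falls below 0.05. On a dense map a
  miscalled singleton's compatible posterior is ≈ r²/(r² + ε) — about
  0.01 on a 1 cM grid with ε = 0.01 — so the threshold must sit above
  that; with a fitted ε near zero (clean data) the same quantity moves
  toward 0.5 and nothing is flagged, which makes the detector
  self-calibrating.
- **Singleton rule** — a call disagreeing with both nearest non-missing
  flanks within 10 cM while the flanks agree. This rule cannot tell a
  miscall from a genuine double crossover, so the pipeline applies it
  only when the fitted ε ≥ 0.005 (data demonstrably noisy); and it is
  restricted to inbred-derived populations, because CP genotype
  classes cannot be compared across markers without phase — a
  "disagreement" between repulsion-phase neighbors is the expected
  pattern, and the posterior method covers CP.

Twins: markers whose non-missing calls agree on ≥ 20 co-typed
individuals and conflict on none (CP: also up to a consistent
within-parent allele relabeling). The representative (fewest missing
calls, ties by name) is mapped; the rest re-attach to the total map.

## Simulator

Meioses are crossover counts ~ Poisson(L/100) with uniform positions —
no interference, making Haldane the exact distance model and the
simulator a calibration-free oracle for the estimators. Markers sit at
0, s, 2s, …, L inclusive (a 100 cM chromosome at 1 cM spacing carries
101 markers). Generation schemes are simulated literally (BC: one F1
gamete over the recurrent parent; DH: one gamete doubled; F2: two
gametes; RILn: n selfing generations per lineage, 20 ≈ fixation;
IRILt: an F2 population, t rounds of random union of gametes, then
selfing; CP: two parents with per-marker informativeness classes drawn
from a default mix of 30% female pseudo-testcross ab×aa, 30% male
aa×ab, 25% ab×ab, 15% fully informative ab×cd — a plausible SNP-array
mix for an outbred full-sib family — and truth phases recorded).
Errors resample the observed code among the marker's other valid codes
at a per-cell rate that is uniform or Gamma(shape, mean/shape) across
markers or individuals (L-shaped at small shape, near-uniform at
large); missing cells are drawn independently first, so the two masks
are disjoint.

What the simulator does **not** emulate: crossover interference,
segregation distortion, sex-specific recombination, clustered or
genotype-dependent missingness, and allele-calling artifacts that
correlate across markers. Passing the simulation benchmarks therefore
demonstrates correctness of the estimators and the pipeline logic
under the stated meiosis model, not robustness to every real-data
pathology.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| order-robustness LOD | 3.0 | conventional 10³ odds gate for framework membership |
| assignment LOD / gap | 6.0 / 3.0 | conservative group membership; ambiguity is declared, not resolved |
| seed/scaffold r window | [0.05, 0.25] | orients seriation; keeps scaffold sparse but able to reach ends |
| seed LOD | 6.0 | seeds must be unambiguous linkage |
| neighborhood/merge LOD | 10.0 | spurious LOD ≥ 10 among tens of thousands of unlinked pairs is essentially impossible |
| emission ε | 0.01 start, EM-estimated in [1e-4, 0.2] | self-calibrating error model (see above) |
| posterior flag threshold | 0.05 | sits above the ≈ 0.01 compatible-posterior of a dense-map singleton |
| singleton window / gate | 10 cM / ε̂ ≥ 0.005 | rule only engaged when miscalls are demonstrably present |
| twin overlap | 20 individuals | below this, identical columns are unconvincing |

## Problem sizes

The test suite exercises the full pipeline on reduced designs (one to
two chromosomes of 40–100 cM, 2 cM spacing, 120–200 individuals) and
reserves the full benchmark design — error-free F2 and CP populations
of 200 individuals on two chromosomes of 100 and 200 cM at 1
marker/cM — for the acceptance layer, where one run takes a few
minutes on a single CPU. The error-correction comparison uses one
100 cM chromosome at 2 cM spacing with 150 individuals and three
replicates per error rate, which reproduces the corrected/uncorrected
separation decisively (uncorrected maps inflate 2–4× at 2–5% error).

## Known limitations

- Single averaged CP map; sex-specific recombination fractions are not
  fitted.
- The robustness statistic bounds single-marker repositioning and
  adjacent flips, not arbitrary multi-marker rearrangements.
- Bins are frozen at placement time; placed markers do not update
  framework distances.
- No interference-aware multipoint model (Haldane throughout; Kosambi
  only as a reporting convenience).
- No consensus-map merging across populations.
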