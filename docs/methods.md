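# Methods

## The model

A multistage (MS^n) experiment on an ion-trap instrument isolates a
precursor ion, fragments it, and iterates: each fragment ion can itself
be isolated and fragmented, up to MS^5 here. Because the fragment ions
observed at stage n are products of a specific precursor isolated at
stage n−1, the run carries an *observed* precursor–product hierarchy —
nothing about the fragmentation chemistry needs to be predicted.

`fragtree` exploits that hierarchy as a system of hard constraints on
elemental-formula assignment:

1. a fragment ion cannot contain more atoms of any element than its
   precursor ion (element-wise sub-formula relation);
2. the fragment formula and the neutral-loss formula must add up
   exactly to the precursor formula;
3. candidate formulas must match the observed m/z within a mass
   tolerance (default 6 ppm), pass heuristic element-count/ratio
   plausibility rules, and have non-integer RDBE (even-electron
   singly charged CHNOPS ions sit on the half-integer RDBE grid).

A peak with no surviving candidate is an artifact (electronic noise,
RF interference, FT side bands) and is discarded. Each surviving ion
is identified by its Elemental Formula Path (EFP): the ordered list of
ion formulas from the root precursor down to the ion, serialized with
`||` separators (`C10H18N3O6S1||C5H11N2O3S1||...`). A fragmentation
tree is equivalently a set of EFPs, which makes trees directly
comparable across compounds.

Working currency: ion compositions with the proton included, charge 1,
polarity ±1. Adducts other than ±H, multiple charges and elements
beyond CHNOPS are out of scope. Theoretical ion m/z includes the
electron mass ((m − polarity·z·mₑ)/z); without it the worked-example
masses do not reproduce at three decimals (308.092 instead of
308.091).

## Candidate enumeration

`enumerate_candidates` iterates over the heavy elements (C, N, O, P, S)
with cumulative-mass pruning and solves the admissible hydrogen-count
interval directly from the residual mass window, so its cost scales
with the number of feasible heavy-atom combinations. The test suite
checks it against an independent exhaustive nested-loop oracle.

Plausibility filters follow the familiar heuristic rule set for small
molecules, in its extended-range form so that ionic fragments are not
falsely rejected: 0.1 ≤ H/C ≤ 6, N/C ≤ 4, O/C ≤ 3, P/C ≤ 2, S/C ≤ 3,
with per-element maxima C ≤ 39, H ≤ 72, N ≤ 20, O ≤ 20, P ≤ 9, S ≤ 10
(the < 500 Da window). All bounds are configurable on
`FormulaConstraints`. Carbon-free formulas are judged on the maxima
only. Isotope-pattern scoring is deliberately absent: the acquisition
protocol isolates monoisotopic precursors, so no isotope information is
available downstream.

RDBE is computed on the *ion* composition as C + 1 − H/2 + (N+P)/2 and
a candidate is kept when the value is a half-integer ≥ −0.5 (−0.5
admits protonated saturated species). Computing on the ion rather than
the neutral is a design choice; for singly protonated/deprotonated
even-electron species the two conventions select the same candidates.

## Assignment algorithm

Assignment is a single top-down pass. The root (MS1 precursor) formula
is either validated against a user-supplied composition or taken as
the best-ranked enumeration candidate. Each scan's peaks are then
enumerated under the cap of the scan's (already assigned) precursor-ion
formula; residual ambiguity — more than one surviving candidate — is
resolved by minimum |ppm|, then lexicographic token order, and the node
is flagged `ambiguous` rather than dropped, preserving auditability. A
peak that was fragmented but received no formula takes its child scans
down with it (logged). A global constraint-propagation refinement over
the whole tree would only matter when a wrong parent assignment blocks
correct children; with 6 ppm tolerance and the hierarchy cap this did
not occur on any packaged input, and it is left as an extension.

Consensus over within-run repetitions keeps an EFP iff it appears in at
least `min_fraction` (default 0.4, inclusive — 2 of 5 survives) of the
single-repetition trees, recording presence fraction, mean and sample
(n−1) standard deviation of the relative intensity, and mean ppm error.
The filter operates on EFPs, where "the same peak" is well-defined
across repetitions; the sample-sd choice is ours (single observation ⇒
sd 0).

## Tree comparison

Trees are compared as EFP sets: Tanimoto coefficient
|A∩B| / (|A|+|B|−|A∩B|), defined as 0 for two empty sets. Collections
become binary occurrence matrices (rows = trees, columns =
lexicographically sorted EFP union) clustered agglomeratively on
Euclidean distance. Default linkage is complete (bottom-up); average
("mean") linkage is exposed as an option because both appear in
descriptions of this analysis. Rows are sorted by label before
clustering so permutation/relabeling cannot change the merge topology.
The cosine ("dot product") comparison of composite spectra — all scans
pooled, peaks coalesced within an m/z tolerance, greedy nearest-match
alignment — is provided as the conventional baseline that tree
comparison improves upon.

## The simulator

The generator emulates the study's acquisition so every pipeline stage
is testable without instrument data: one full scan, then data-dependent
selection of the top-5 peaks of each MS2 and MS3 spectrum and top-3 of
each MS4 spectrum, to MS5; precursors must exceed 4500 ion counts. A
scheme that saturates (every spectrum offers enough fragmentable peaks)
emits 1 + 1 + 5 + 25 + 75 = 107 scan events per repetition.

Noise defaults are the study conditions: mass noise σ = 1 ppm
(bracketing the worked example's −1.0…+1.7 ppm observed errors),
multiplicative log-normal intensity noise with CV = 2% (observed
relative-intensity standard deviations were typically below 2%), five
repetitions, and 0.5 expected artifact peaks per scan. Artifact m/z
values are rejection-sampled to lie more than twice the tolerance away
from every sub-formula ion mass of the scan's precursor, so "artifact"
is well-defined at generation time; artifact intensities sit below the
precursor threshold, as the real interferences (RF pickup, side bands)
are low-intensity signals that DDA never fragments. Absolute scale is
arbitrary in the real data (per-spectrum relative intensities are the
recorded quantity); the simulator uses 10⁶ counts for the root and a
per-level attenuation of 0.5, which keeps every true branch of the
packaged fixtures above the 4500-count threshold, matching the
high-concentration regime in which the full tree is observed. One
master seed drives everything; per-repetition generators are spawned
deterministically from it.

What the simulator does *not* emulate: fragmentation chemistry
(collision-energy and isolation-width trends are instrument effects),
isotope envelopes (excluded by the isolation protocol), chromatography,
ion-trap low-mass cutoff, detector saturation. Passing tests therefore
demonstrate the correctness of the tree-construction logic under the
stated noise model, not instrument-level robustness.

The glutathione worked example ships as a data fixture: 21 EFPs with
MS level, relative intensity, observed ppm error and intensity
standard deviation. Rebuilding the spectra from the *theoretical*
masses perturbed by the recorded ppm errors and re-running assignment
recovers all 21 EFPs verbatim — the package's primary end-to-end check.
The isomer-pair generator builds two same-root truth trees with
prescribed EFP-set sizes and overlap (default root C20H31O5, a
deprotonated prostaglandin), used for the 25/31/13 set-arithmetic and
clustering demonstrations; since the root EFP is always common, an
overlap of zero is correctly rejected as infeasible.

## Numerical choices and degenerate inputs

- Monoisotopic masses: H 1.00782503207, C 12 (exact), N 14.0030740048,
  O 15.9949146196, P 30.97376163, S 31.97207100; electron mass
  0.00054857990946 Da.
- ppm errors are measured against the theoretical ion m/z (signed).
- Precursor linking uses an absolute m/z window (default 0.5, half the
  2 m/z isolation width) and the most-recent-parent rule when several
  level-(n−1) scans match; an explicit precursorScanNum wins when
  consistent. Orphan scans are dropped with a log record.
- A new MS1 scan opens a new repetition of the MS^n sequence.
- Composite-spectrum binning coalesces m/z-sorted peaks greedily within
  the bin tolerance (intensity-weighted mean m/z, summed intensity).
- Empty enumeration results, empty scans after filtering, and root-only
  trees are valid outcomes, not errors; an unassignable *root* is an
  error because nothing downstream is defined without it.
- JSON exports are deterministic (sorted keys and children), so
  identical inputs give byte-identical files.

## Problem sizes

The packaged analyses are desk-scale by construction: the glutathione
tree has 21 nodes over 15 scans per repetition, simulated runs use 5
repetitions (75–535 scans), the property suite covers 100 random truth
trees and enumeration targets up to 350 Da. Everything runs in minutes
on one CPU.

## Known limitations

- Only mzXML is read (open, preserves precursor attributes); mzML and
  mzData readers are a documented extension point.
- Peak picking is out of scope; inputs must be centroided. Only a
  simple absolute/SNR threshold gate is provided.
- The CML export is a documented subset (molecule list + per-level
  spectra with precursor references), not full schema conformance.
- Structure-level (bond/InChI) annotation of fragments is out of scope.
- Between-lab reproducibility and real prostaglandin/eicosanoid raw
  data are outside what the synthetic fixtures can establish.
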