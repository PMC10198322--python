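# Methods

## The semi-orthogonal height model

The model reduces a 3-D picture — nucleotide vectors of magnitude A0
standing perpendicular to the strand axis, G/C in one plane (σ) and A/T in
a second plane (ρ) inclined at α = 90° − ψ to the first — to the only
quantity the score needs: the signed projection of each vector onto the σ
axis. Complementary bases point in opposite directions, so

    h(G) = +A0,  h(C) = −A0,  h(T) = +A0 sin ψ,  h(A) = −A0 sin ψ.

The published description of the system states the geometry but not the
numeric magnitudes or signs. The constants used here (A0 = 3, T positive,
A negative, signed — not absolute — area, polyline spanning positions
1…n with no closure to zero at the ends) were fixed by calibration: they
are the unique assignment of the stated geometry that reproduces all 18
published two-decimal Qs values of the nine-oligo validation set (GT and
GA repeats of 6/9/18/27 units and the 31-nt VK motif) at ψ = 15° and 30°.
Each choice is forced by a different part of that table: the sign of T/A
by the GT rows rising and GA rows falling with ψ; signed area by the VK
row, whose four C's must subtract; the open-ended polyline by the
(n−1)/n trend across lengths. The calibration is re-executed as a test.

Qs = (area under the height polyline)/n. Sequences with n ≤ 1 score 0 (a
single point subtends no area). ψ is accepted in degrees everywhere;
radians are internal. Ambiguity codes normalize to a neutral placeholder
of height 0 and are counted rather than rejected, so genome-scale FASTA
input never aborts; RNA U is read as T.

Two printed cells ((GT)₁₈ and (GT)₂₇ at ψ = 30°: model 2.1875 and 2.2083,
printed 2.18 and 2.20) differ from round-half-away rounding by exactly one
unit in the last digit, consistent with truncation; golden tests therefore
assert agreement within ±0.015 of the two-decimal values, which covers
both conventions and is tighter than any band that matters.

## Score bands

Classification is defined at ψ = 30 (α = 60, the optimal angle for G4
prediction): Qs > 2 Z-G4-prone, 1.2 < Qs ≤ 2 G4 candidate, 0.7 ≤ Qs ≤ 1.2
tetrahelix band, Qs < −1.2 i-motif candidate. The tetrahelix band is
usually quoted as 0.7–1.1 at print precision, but its defining member (VK)
scores 1.1129 under the model, so the band's real upper edge is the G4
threshold itself; the lower edge is sharp — a 6-unit GA repeat scores
0.6875 and stays unfolded experimentally, while 9 units (0.7083) folds.
The i-motif edge is the exact mirror of the G4 threshold, which the
complement antisymmetry of the score makes the only non-arbitrary choice.
Classification at ψ = 15 is not defined (the bands were established at 30
only).

## Scanner

Windows are 25 nt by default — wide enough to span the shortest
motif-forming repeats ((GT)₈ = 16 nt) with margin — at step 1, emitting
intervals where |Qs| ≥ 1.2; overlapping same-strand windows merge to
maximal intervals retaining the extremal window score. Records shorter
than the window are scored whole; final partial windows are skipped by
default because the (n−1)/n factor biases them low. Coordinates are
0-based half-open internally and in BED, 1-based inclusive in the TSV.

Window scores and sub-window "core" scores have different null
distributions: a core of 12–15 nt drawn from random background reaches
Qs > 2 orders of magnitude more often than a 25-nt window does. Labelling
scanner calls by their best short core would therefore manufacture
Z-G4-prone calls from generically G-rich background. The default pipeline
(`annotate_sequence`) consequently labels scanner calls from their window
scores and reserves above-window-resolution classification for exact
dinucleotide tracts, which are the sequences the Z-G4 band is about; a
(GT)₈ tract inside a 25-nt window is promoted by its tract score (2.109),
not by a free-floating core search. `refine_call` exposes the core search
as an explicit opt-in trimming utility with this caveat documented.

The repeat finder reports maximal alternating runs of a unit (both
phases; complements as minus-strand tracts), with the count of full units
and a flag for a dangling half unit. Default minimum is 6 units with a
"confident" tier at 8, encoding the observed critical range of six to
eight GT/GA repeats for motif adoption.

## Melting-curve analysis

The two-state model with linear folded/unfolded baselines,

    S(T) = (b_f + m_f T)·f + (b_u + m_u T)·(1 − f),
    f = K/(1+K),  K = exp[−(ΔH/R)(1/T − 1/Tm)],

is fit by nonlinear least squares (scipy `curve_fit`), Tm initialized from
the derivative estimator and baselines from the outer 15% of points. ΔH
is the apparent van't Hoff enthalpy, negative for a transition folded at
low temperature; ΔS is not an independent parameter (ΔS = ΔH/Tm follows
from the midpoint convention), giving ΔG(T_ref) = ΔH(1 − T_ref/Tm) with
T_ref = 0 °C by default. Temperatures are Celsius at interfaces, kelvin
inside. Non-convergence raises with diagnostics; a fitted Tm within 5% of
the range edge sets a warning flag rather than failing.

Molecularity m > 1 is exposed for multimeric folds of unknown strand
concentration: the folded fraction solves θ/(1−θ)^m = g(½)·K(T), which
preserves θ(Tm) = ½ without a concentration term and changes only the
steepness. It is not the default, since the stoichiometry of the (GA)n
structure is an open question.

The derivative Tm estimator resamples the curve onto a uniform grid in
1/T(K) — the coordinate in which a two-state transition is exactly
symmetric — smooths with a Savitzky–Golay filter (window ≈ n/10, order 3)
and takes the parabola-refined extremum. Working in inverse temperature
removes the low-temperature skew the dS/dT extremum acquires for broad
transitions (≈ 1 °C at ΔH = −100 kJ/mol), keeping the estimator within
1 °C of the full fit across the tested grid. Significance is judged by
propagating a second-difference noise estimate through the derivative
filter coefficients (peak must exceed 5× the derivative noise and must be
interior), so flat curves, pure noise and pure linear drift fail
explicitly. Heating-rate/hysteresis effects are out of model and carried
as metadata only.

## Synthetic data

Generators are NumPy PCG64-seeded and byte-reproducible. Random genome
background is i.i.d. with configurable GC fraction (default 0.5; the Qs
null depends on GC), which emulates none of the repeat-length structure,
composition heterogeneity or mutational correlation of real genomes —
spike-in recall and the empirical null measured on it bound scanner
behaviour on that idealized background only, not false-positive rates on
real chromatin. Spiked genomes place repeat oligos at stated offsets
(overlaps rejected) and emit a BED-like truth table. Melt curves are
simulated from the same two-state model the fitter uses (with noise given
as a fraction of the folded/unfolded amplitude at Tm), so recovery tests
validate the optimizer and estimator, not the physical adequacy of the
two-state assumption.

## Problem sizes and defaults used in validation

The validation suite scores the nine-oligo calibration set exactly;
property tests run 1,000 random sequences of ≤ 60 nt against a
shoelace-polygon oracle; scanner recall uses four spiked and twenty null
10-kb genomes at window 25; melt recovery uses a 3 × 3 grid of
Tm ∈ {40, 55, 70} °C × ΔH ∈ {−100, −200, −350} kJ/mol at 1% noise with
three replicates each on 201-point curves, asserting median |ΔTm| < 0.5 °C
and median relative ΔH error < 5%.

## Known limitations

Only the σ-axis (G/C-plane) projection is implemented; a possible
independent use of the ρ-plane profile for A/T-rich motifs is not. The
scanner asserts nothing about which candidates actually fold — the bands
are sequence propensities, and folding depends on conditions (crowding,
cations) outside the model. No multi-transition deconvolution, no
hairpin/cruciform calling, no GFF intersection.
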