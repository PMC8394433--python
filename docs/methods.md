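# Methods

## Model

A microsatellite locus is summarised by the histogram of inter-flank
lengths observed in its reads. PCR and sequencing-library amplification
introduce replication slippage, so even a single allele produces a
stutter-broadened distribution. The central modelling assumption is that
this stutter shape is a property of the locus and the chemistry, not of
the allele: an unstable allele produces the *same* empirical shape
translated along the length axis. The observed distribution is therefore
modelled as

    f(x) = Σ_{n=1..3} P_n · g(x; m_n),

where `g(·; m)` is the empirical reference profile of the locus
(estimated from pooled MSS controls) relocated so its expectation is `m`,
`P_n ≥ 0`, `Σ P_n = 1`. Up to three components cover one stable plus up
to two unstable alleles. Relocation by a fractional offset interpolates
linearly between the two adjacent integer translations, which preserves
the empirical shape and makes the component expectation exact.

The reference profile itself is the normalized pooled control histogram
over the observed range padded by ±3 bins, floored at a pseudocount
(default 1e-6 per bin, renormalized). The floor keeps log-likelihoods
finite when a test sample shows lengths unseen in controls; the padding
absorbs sampling noise at the support edge. No parametric (e.g. normal)
form is used anywhere: observed stutter distributions are asymmetric and
locus-specific, and a location family built on the empirical shape
matches them by construction.

## Extraction

Reads are used unaligned and unfiltered. A read contributes one
observation to a locus when both of the locus' flanking sequences anchor
on the same orientation of the read (forward or reverse complement),
with a local-alignment score of at least `min_score_fraction` (default
0.8) of the flank's perfect-match score (unit match/mismatch, gap open 2,
gap extend 1; `N` counts as a mismatch against everything). The
observation is the *full* inter-flank span length, provided the trimmed
sequence passes the homopolymer rule (longest run of the repeat base ≥ 8
nt and ≥80% repeat-base content): sequencing errors inside the run do
not change the measured length, exactly as internal sequence does not
change an amplicon's electrophoretic mobility. Both mates of a pair are
counted independently; no deduplication is attempted, since amplicon
libraries are themselves clonal.

Implementation note: anchoring first tries exact substring search; the
Smith–Waterman fallback (Biopython `PairwiseAligner`) is gated by a
three-seed prefilter. At the default threshold an accepted anchor can
carry at most two edits, so by pigeonhole at least one of the three
flank thirds occurs exactly and the gate rejects nothing that the
aligner would accept; at much looser thresholds the gate becomes a
heuristic.

## EM fit

The fit operates on the binned histogram (a sufficient statistic — the
likelihood is identical to the per-read form). The E-step computes bin
responsibilities; the M-step separates into the classical proportion
update and one one-dimensional location problem per component, because
the expected complete-data log-likelihood is additive over components.
Each location problem is solved by scanning every integer translation of
the profile (one matrix–vector product against a precomputed
log-translation table) followed by a bounded fractional search
(Brent, xatol 1e-3) in the winning unit interval; the previous mean and
the responsibility-weighted mean are retained as candidates. Since every
accepted update does not decrease its surrogate share, the
log-likelihood is monotone non-decreasing by construction — this holds
even though the deletion-skewed stutter shape makes the plain
responsibility-weighted-mean update non-optimal (using that moment
update alone was observed to stall: it is not a fixed point of the
likelihood for skewed shapes, so the algorithm oscillates below the
optimum).

Numerical schedule: integer-resolution updates until the log-likelihood
gain drops below the tolerance, then fractional refinement to final
convergence (tolerance 1e-6, max 500 iterations). During the slow tail
of EM — a near-zero component's proportion decaying geometrically — the
means are stationary, the fractional search result is cached per integer
anchor, and each iteration reduces to array arithmetic.

Initialization: component 1 at the reference mean with proportion 0.90;
components 2 and 3 at offsets −5 and −10 nt with proportions 0.05
(deletion-biased starts reflecting poly-A instability); three restarts
with seeded Gaussian jitter (SD 2 nt) on the offsets so insertions are
explored. Components ending within 0.25 nt of each other are merged
(proportion-weighted) before reporting, preventing one allele from being
double-counted. The best restart by final log-likelihood is reported. A
grid-search oracle test (exhaustive sweep over mean × proportion) bounds
any residual optimisation gap at 0.5 log-units on two-component
problems.

## Decision cascade

Per locus, with reference mean `μ`:

1. component `n` is stable iff `|m_n − μ| ≤ 0.10·μ` (boundary inclusive);
2. all components stable, or unstable components jointly < 2% of the
   mixture → **stable**;
3. otherwise a likelihood-ratio test compares the full fit with a
   reduced model refitted using only the stable components, their means
   confined to the stable band. The confinement matters: at high
   unstable fractions (e.g. a ~75% positive control) an unconstrained
   one-component null would park on the unstable mode and mask the
   instability. The statistic `2(ℓ_full − ℓ_reduced)` is referred to a
   chi-square with 2 degrees of freedom per removed component (mean +
   proportion) — boundary effects make this conservative, which favours
   specificity;
4. significant (α = 0.01 by default) → **unstable**, reporting each
   retained unstable component's proportion and mean shift; a single
   unstable component at 50 ± 10% proportion additionally raises a
   germline-polymorphism flag;
5. not significant → the Monte-Carlo power of the test at the observed
   depth, against the minimal-instability alternative (2% unstable
   alleles shifted −6 nt), decides: power > 80% → **stable**, else
   **non-contributory**. The power simulation measures rejection by the
   LRT itself, not the whole cascade: the 2% proportion gate is a
   separate guard, and because the alternative sits exactly at that
   gate, including it would cap estimable power near 50% at any depth.

Histograms with fewer than `min_reads` (default 50) observations are
non-contributory outright. Bisection over the power curve
(`min_reads_for_power`) reproduces the per-locus minimum coverage needed
for interpretability; with the synthetic stutter model the 80% gate is
cleared around 200–300 observations, lower than FFPE practice because
the simulated noise is cleaner than real libraries.

Sample level: ≥2 unstable loci → **MSI**; otherwise **MSS** provided ≥4
loci were contributory, else the sample is non-contributory (a
configurable safeguard — an MSS claim from two interpretable loci is
clinically unsafe; the published rule set never meets this case).

Power estimates are cached per (locus, ~10% depth bucket) within a run,
and the EM inside power replicates uses a single deterministic start
with a 1e-4 tolerance — power needs the verdict, not a polished fit.

## Simulator

`simulate` emits paired 150-nt reads whose fragments carry
flank5 + repeat-run + flank3 embedded in random context, both mates
covering the insert, constant base qualities (the caller ignores
qualities). Slippage noise: with probability `a` the run length is
offset by a Geometric(p) magnitude, deletions three times as likely as
insertions; `(a, p)` are calibrated so the offset SD equals the
requested `stutter_sd` (p starts at 0.7 — stutter is mostly ±1 nt — and
relaxes only for large SDs). The closed-form pmf and moments make the
model auditable by exact chi-square and moment tests. Defaults mirror
the study conditions: stutter SD 1 nt, depth 2000 read pairs per locus,
unstable shift −6 nt, dilution ladder 1/4…1/20 of a positive control
with 73–77% unstable alleles per locus.

Synthetic loci reuse the Bethesda run lengths (25, 26, 21, 24, 27 nt
poly-A) but carry random 20-nt flanks free of ≥4-nt runs of the repeat
base, with the repeat-adjacent flank base forced off the repeat base
(mimicking primer design and keeping the inter-flank span unambiguous).

What the simulator does *not* emulate: substitution sequencing errors in
flanks (exercised by dedicated fixtures instead), FFPE artefacts,
locus-specific stutter asymmetries beyond the 3:1 deletion bias, depth
variation across loci, or contaminating non-target amplicons. Passing
tests therefore demonstrate the correctness of the algorithmic chain
under the stated noise model, not clinical performance on FFPE
libraries.

## Study-scale choices

The in-silico limit-of-detection ladder uses fractions
{18.5, 9.3, 6.2, 5.0, 3.7}% — a positive control of ~74% unstable
alleles through the 1/4…1/20 dilution ladder — with 20 seeded replicates
per fraction at depth 2000/locus; the detection limit is the smallest
tested fraction called MSI in ≥90% of replicates. Linearity regresses
the EM-quantified unstable proportion on the expected fraction across
the undiluted control plus the five dilutions, three seeds, reporting R²
per locus. Reference profiles for these studies pool four simulated MSS
controls of 5000 read pairs per locus.

## Known limitations

- The chi-square reference for the LRT ignores the boundary nature of
  the hypothesis (proportions at 0); the test is conservative.
- The ±10% stable band scales with the reference mean, so short loci
  (NR-21) tolerate smaller absolute shifts than long ones — a property
  inherited from the published rule, not a modelling choice.
- Fractional relocation by linear interpolation slightly widens a
  component (adds up to 0.25 bin² of variance at half-integer shifts);
  negligible against stutter variance ≥ 1.
- A germline microsatellite polymorphism is flagged, not resolved; a
  matched normal sample remains the only way to settle it.
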