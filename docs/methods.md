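# Methods

This note documents the models, numerical choices, and open design decisions
behind `abzinc`, and what its synthetic-data tests do and do not demonstrate.

## Calorimetric binding model (`abzinc.itc`)

**Forward model.** Zinc binding to the peptide in the cell is described by one
or two *independent classes* of sites, the standard data-reduction model of
MicroCal-type instruments. After injection k the cumulative injected volume
ΔV gives the displacement-corrected total concentrations

    M_t = M0 (1 − ΔV/2V0) / (1 + ΔV/2V0)
    X_t = X0 (ΔV/V0) (1 − ΔV/2V0)

(perfusion/overflow convention). The free ligand L solves the mass balance
`X_t = L + M_t Σᵢ Nᵢ Kᵢ L/(1+Kᵢ L)`; because the left-hand side is strictly
increasing in L on [0, X_t], L is found by vectorised bisection (52 halvings,
bracket width < 2·10⁻¹⁶ X_t, far below the 10⁻¹⁰ relative tolerance the heats
need). The measured per-injection heat is
`ΔQ_k = Q_k − Q_{k−1} + (dV_k/V0)(Q_k + Q_{k−1})/2`, normalised per mole of
injectant. Heats are carried in kcal throughout, matching the units of the
published thermodynamic table. Tests verify the simulator against an
independent dense-grid + scalar-bisection solver to 10⁻⁸ relative over random
parameter draws.

**Default protocol.** 20 injections of 2 µL of 5 mM ZnCl₂ into 0.2 mL of
0.3 mM peptide at 25 °C — the experimental protocol; the injection count is
the generator's choice (the experiments state only "to obtain a complete
binding isotherm"; 20 × 2 µL spans molar ratios up to ≈ 3.7, well past the
combined equivalence point of 1.35).

**Fitting.** Non-linear least squares (`scipy.optimize.least_squares`, TRF)
on per-injection heats, parameterised per site as (N, log₁₀K_a, ΔH).
Multistart initialisation over K_a ∈ {10³, 10⁴, 10⁵, 10⁶} M⁻¹ (ordered pairs
for two sites), N ∈ {0.3, 1.0} for the minority site, and ΔH from a
total-heat heuristic. Bounds express prior plausibility for zinc–peptide
calorimetry: N ∈ [0, 3] sites/peptide, log₁₀K_a ∈ [2, 8] (the Wiseman
c = K_a·M window caps what a titration can resolve), ΔH ∈ [−30, 30] kcal/mol;
without them the fit admits degenerate optima with N → 0 and |ΔH| → ∞ at
finite N·ΔH. Uncertainties come from a seeded residual bootstrap (default
200 resamples, refit from the best solution). Replicate spread across seeded
synthetic repeats is reported separately by the recovery studies, since the
published ±15/25/20 % figures could be either fit uncertainties or replicate
spread.

**Model selection.** One versus two site classes by small-sample-corrected
AIC on the residuals; the two-site model must improve AICc by more than 2.
A flat zero-heat curve is rejected as indeterminate rather than fitted.

**Known identifiability limit.** Under the synthetic default of 2 %-of-maximum
Gaussian noise, the published two-site parameter set (sites at −10.3 and
−8.0 kcal/mol with overlapping transitions) leaves the high-affinity site
weakly identified: the Fisher information at the true parameters gives
sd(N_high) ≈ 0.18 (half the parameter) and sd(log₁₀K_high) ≈ 1.6, and the
least-squares optimum itself — even when started at the truth — drifts along
a ridge toward large K_high and inflated N_high. The same machinery recovers
all parameters to well within the reported tolerances at 0.5 % noise, and the
low-affinity site and one-site mutants are recovered accurately at 2 %. This
is a property of the study conditions, not of the optimizer; it is reported
as measured.

## Zinc-chelator localization (`abzinc.ms_mapping`)

**Fragments and adducts.** Terminal b/y (CID) and c/z-dot (ECD) series plus
b-type internal fragments (double backbone cleavage, no rearrangements;
a/x ions and neutral losses are excluded by default). C-terminal amidation
(−0.98402 Da versus the free acid) applies to y/z and whole-peptide masses.
Each retained zinc shifts the neutral mass by Zn − 2H = +61.91349 Da, charge
being carried by protons — the standard electrospray metal-adduct
bookkeeping. A fragment may carry at most as many zinc ions as it has
chelation-capable positions (Asp, Glu, His, Cys, Met, Tyr, plus the free
N-terminal amine as pseudo-position 0; the set is configurable, and Gly/Ala
are rejected outright). Masses derive from the pyteomics residue table and
are tested against an independently transcribed table to < 10⁻⁴ Da.

**Annotation.** Peaks match theoretical fragments within a ppm tolerance
(default 5, an FT-ICR-class figure). Ties prefer fewer zinc, then lower
charge, then terminal over internal series, then smaller mass error; when
the precursor's zinc count is known it caps the assignments.

**Inference.** The chelator report is built in five switchable steps:
(1) pool zinc-carrying assigned spans across spectra (discarding chemically
impossible assignments); (2) keep *minimal* spans — no assigned sub-span at
the same zinc count; (3) score: each minimal span carrying k zinc apportions
k units of evidence equally among the capable positions it covers, weighted
by the number of spectra showing the span, and scores are normalised to a
maximum of 1. Apportioning (rather than scoring bare containment) prevents a
bystander capable residue inside one broad multi-zinc span from reaching the
acceptance threshold; containment scoring remains available via
`scoring="containment"`. (4) Cleavage-suppressed regions: inter-residue
sites cleaved in apo spectra but never in holo spectra (runs of length ≥ 2),
read as possible zinc bridges. (5) Final candidates: capable positions with
normalised score ≥ 0.5 plus capable positions interior to suppressed regions,
ranked by score. Dimer spectra are treated at monomer composition, since the
coordinators in monomer and dimer complexes are equivalent. The exact scoring
used by the original analysis is not public; this reconstruction is explicit
and auditable rather than guaranteed identical.

**The N-terminal amine** participates as a capable pseudo-position by default
(it coordinates zinc in the binuclear N-terminal site of the mutant); its
evidence is inherently confounded with residue 1, so planted-recovery tests
plant chelators at positions ≥ 3.

## Contact census and interface selection (`abzinc.contacts`)

A frame is a contact when the *minimum side-chain heavy-atom distance*
between two residues is strictly below the cutoff (default 4.5 Å); atom scope
(side-chain vs all heavy) is configurable and recorded in outputs, since the
original census does not state it — for the same reason the published
20,000-frame counts are not asserted as reproducible targets. Censuses are
exact per frame and tested against an O(n²) loop oracle; identical inputs
produce byte-identical census tables. Conformational clustering of dimer
structures is out of scope; the per-pair frame census carries the same
decision content. Interface selection then: drops pairs never seen in
contact; discards every member of a mutual-exclusion group when more than one
member has contact evidence (E3/H7 with H6/H13 cannot exist concurrently in
one molecule); removes sterically impossible pairs (H6/H13); and emits the
survivors as symmetric zinc interfaces around the anchor E11/H14 (the only
high-affinity class). On a census with the published evidence pattern this
yields exactly E11/H14:ZN:E11/H14, E3/H6:ZN:E3/H6, and H7/H13:ZN:H7/H13.

## Assembly combinatorics (`abzinc.assembly`)

Subunits expose variant-specific interface sites (WT: E11/H14, E3/H6; D7H
additionally H7/H13; isoD7: E11/H14, H6/H13); a bridge holds exactly one zinc
and one site per endpoint. Compatibility: the three homotypic interfaces
pair with themselves; E11/H14 additionally pairs with H7/H13 and H6/H13 (the
heterotrimer wiring); a strict homotypic-only mode exists. Under the default
seed-recruitment rule a WT subunit engages only its E11/H14 site and only
with a modified partner — WT alone stays monomeric with zinc, and WT E3/H6
is inert (the pure-mutant lattices are modelled with the rule switched off
or with D7H subunits).

**Seeds.** Two structural observations govern growth: the E11/H14 dimer is
the polymerization unit, and a subunit whose E11/H14 is already zinc-bridged
cannot re-form its intramolecular H7/H13 (or H6/H13) pair to recruit a new
subunit — those interfaces arise concurrently with EVHH dimerization, not
sequentially. A *seed* (default `unit="dimer"`) is therefore a pair of
same-type free, conformationally available sites on the two subunits of one
EVHH dimer, where an incoming dimer can dock with two bridges. A free-site
count alone cannot reproduce the published three seeds of the dodecamer: every
bridge consumes two site slots, so the free-slot count of a pure-D7H
12-mer is always even. Single-site (`unit="monomer"`) counting is retained
and drives `can_extend`, which also covers heterotrimer-style single-bridge
recruitment.

**Named topologies.** The standalone tetramers join two EVHH dimers with two
second-type bridges. The octamer and dodecamer chain EVHH dimers with one
shared zinc per named interface; the dodecamer consists of three tetramer
blocks — H7/H13-closed, E3/H6-closed, H7/H13-closed — linked through one
E3/H6 and one H7/H13 inter-block interface. (A dodecamer built purely from
two-bridge tetramers cannot be connected under homotypic compatibility:
an H7/H13-closed block exposes only E3/H6 sites while an E3/H6-closed block
exposes only H7/H13 sites.) Under the seed rules this wiring yields exactly
three lateral dimer-docking slots by pure graph counting. Orientation
(parallel/antiparallel) is carried as an annotation only; no coordinates are
modelled. The possible E3/H13 + H6/H7 interface in larger systems is excluded
by default but representable through custom rules.

## Synthetic data (`abzinc.synthetic`)

All generators are seeded and byte-identical under regeneration; each dataset
ships with a ground-truth manifest sufficient to re-derive every assertion
made about it.

* **Isotherms**: ideal forward curves plus i.i.d. Gaussian noise scaled to
  the largest |heat| (default 2 %); no baseline drift, integration error, or
  first-injection artefact. Passing recovery tests therefore demonstrates
  estimator correctness under idealised noise, not instrument robustness.
* **Spectra**: clean fragment ladders at a coverage fraction shared between
  apo and holo spectra (so coverage gaps cannot mimic cleavage suppression),
  plus planted zinc evidence. Pinned mode plants, per chelator, the smallest
  mass-resolvable span containing it and no other capable residue — spans
  grow through non-chelating neighbours until their m/z is unambiguous under
  the annotation tie-breaks, since e.g. every single-His internal fragment is
  isobaric. Grouped mode plants one span per group of nearby chelators (plus
  a k-zinc group span), reproducing the worked-example pattern over residues
  3–7 and 11–14. Decoy peaks are placed ≥ 20 ppm from every theoretical
  fragment. No isotope envelopes or intensity structure.
* **Trajectories**: one backbone and one side-chain centroid atom per residue
  (7 Å spacing, 50 Å between chains); controlled pairs draw per-frame
  Bernoulli contacts at Uniform(3.2, 4.4) Å versus Uniform(6, 12) Å, and all
  uncontrolled pairs stay above 6 Å by construction. A residue may be
  displaced by at most one controlled pair; conflicting constraints are
  rejected as geometrically unsatisfiable. The demo rates keep the qualitative
  zero/nonzero pattern of the published 20,000-frame dimer census but are
  scaled up so a 2,000-frame run (the default test scale, chosen for runtime)
  shows every nonzero pair with high probability.

## Problem sizes used by the shipped studies

Recovery studies use 50 seeded replicates per condition; censuses in tests
use 200–2,000 frames; fragment-mass and free-ligand oracle suites use 500 and
100 random draws respectively. These sizes are the package's defaults for a
desk-scale reproduction and are configurable.

## Known limitations

* The two-site fit's high-affinity stoichiometry is biased at the default 2 %
  synthetic noise (see above); conclusions about that site should rely on
  lower-noise data or replicate medians of the low-affinity parameters.
* The intersection algorithm reconstructs an undisclosed procedure; its steps
  are switchable precisely so its behaviour can be audited.
* The assembly model is graph-level: no thermodynamic weighting of topologies,
  no kinetics, and no atomistic geometry beyond the two conformational rules
  stated above.
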