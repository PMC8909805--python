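# Methods

## The screening model

A pharmacophore query is an abstract interaction point — aromatic,
hydrophobic, hydrogen-bond donor or acceptor — at a fixed position in the
receptor frame with a spherical distance tolerance. The DVL1 selectivity
model ships with seven queries: three aromatic anchors (the dimethylphenyl
site engaging the Arg69/Arg72 pair, the indole site at Val68, the pyridine
site at Ile14/Val75), one donor point for the indole-NH backbone hydrogen
bond, one acceptor point for the carboxamide oxygen, one generic hydrophobic
anchor, and the *required* hydrophobic query for the Leu12/Val75/Ile81
sub-pocket that distinguishes the DVL1 groove from NHERF1 PDZ1. Polar
queries use a 2.0 Å tolerance, hydrophobic and aromatic queries 2.5 Å; a
pose is accepted when it matches at least five queries including every
required one, with aromatic and hydrophobic features mutually
interchangeable.

No experimental coordinates exist for the query points (the receptor model
behind them is not public), so the default geometry is an idealised
right-handed frame consistent with the described binding mode:
aromatic–aromatic centroid separations of 5.0–5.2 Å, donor and acceptor
points placed at chemically plausible hydrogen-bond geometry, and — a
deliberate package-level constraint — every inter-query separation above
4 Å, strictly larger than any tolerance sphere plus the generator's 1.5 Å
placement cap. That margin is what lets the synthetic-library decoy
guarantees below hold by construction. The donor query is interpreted as
the indole NH and the acceptor as the carboxamide oxygen; the binding-mode
description admits other polar assignments (a second amide NH, the pyridine
nitrogen), and this choice is an explicit assumption, not a derived fact.
Only the algorithmic behaviour depends on the frame, not any absolute
coordinate, so the arbitrary frame is immaterial to what the tests
establish.

## Feature perception

Perception is deliberately rule-based and deterministic: aromatic features
are the smallest rings (5 or 6 atoms, via a minimum cycle basis of the bond
graph) whose atoms are all aromatic-flagged, centred on the ring centroid;
donors are N/O atoms bearing at least one hydrogen (explicit, RDKit-derived,
or implied from standard valence); acceptors are non-positively-charged
oxygens and hydrogen-free non-amide nitrogens; hydrophobic features are
connected components of ≥ 3 non-aromatic carbons untouched by heteroatoms
(centroid of the component) plus single-atom points for methyls on aromatic
rings. No directional information (ring normals, lone-pair projections) is
used — matching is purely distance-based, mirroring a tolerance-sphere
screen. Hydrogens need not be present in the input; for hand-built
molecules without hydrogen counts, aromatic nitrogens default to
pyridine-type (no implied H).

## Matching and scoring

Pre-aligned matching is solved exactly as a rectangular linear assignment:
squared query–feature distance is the cost of each kind-compatible
within-tolerance pair and a large sentinel penalises infeasible pairs, so
the optimum first maximises the number of matched queries and then minimises
the matched-pair RMSD — the documented tie-break. This was validated
against brute-force enumeration of all injective kind-compatible assignments
on hundreds of random small instances.

The published screen's scoring function is not public, so fitness is defined
here as `n_matched − mean(distance/tolerance)` over matched pairs. It is
unit-free, bounded in `(n_matched − 1, n_matched]`, and therefore preserves
the two orderings the protocol relies on: more matched features always beat
fewer, and tighter geometry wins within a match count.

Align mode searches a rigid transform jointly with the assignment: when the
number of candidate injective assignments is below 10⁵ every assignment of
size ≥ 3 is Kabsch-superposed and kept if all pairs land inside tolerance
(exact); otherwise 3-pair seeds whose internal distance geometry is
consistent within summed tolerances are aligned and greedily extended with
re-assignment/re-alignment rounds. Kabsch superposition enforces a proper
rotation (determinant +1) via the standard SVD sign correction. Whether the
original campaign re-aligned poses is unknown; since its poses came from
docking, the screen defaults to the pre-aligned frame and align mode is an
explicit extension.

## The screening pipeline

Each molecule is represented by its best-fitness conformer; conformers are
grouped by a `MOL_ID` SDF property so record order is irrelevant. Output is
sorted by fitness (descending, ties broken by molecule id for permutation
invariance), and ranks 1..K are carried only by accepted molecules up to the
shortlist size (default 500, the protocol's visual-inspection budget; the
inspection itself is out of scope). A molecule with fewer than the expected
10 conformers is screened with a warning rather than rejected — the 10 is a
protocol parameter, not a validity rule.

## Synthetic libraries with planted truth

The generator emulates the *structure* of the original ~7000 × 10 screen at
desk scale (default 200 molecules × 10 conformers) with minimal synthetic
scaffolds chosen to trigger the perception rules — benzene hexagons,
three-carbon alkane patches, an amine nitrogen, a carbonyl oxygen — rather
than drug-like chemistry: the surface under test is geometric matching.

Actives plant one fragment per selected query (always including required
queries, total drawn uniformly between `min_match` and the query count) with
the feature point displaced from the query centre by a uniform radius capped
at `min(tolerance − 2·jitter_sd, 1.5 Å)` plus Gaussian jitter truncated at
2 sd, the sum hard-clipped to `min(tolerance, 1.5 Å)`. The 1.5 Å cap,
combined with the model's > 4 Å inter-query separations, guarantees a
planted feature can never stray into a different query's sphere. One
conformer per active is the planted pose; the others are rigidly displaced
by `max_separation + 2·max_tolerance + 1 Å`, which provably clears every
sphere. Decoys violate acceptance in one of four modes, cycled across decoy
molecules: `missing_required` (all non-required queries planted — high
fitness, still rejected), `too_few_features` (`min_match − 1` planted),
`displaced_beyond_tolerance` (full set, then globally displaced),
`kind_mismatch` (polar and apolar fragment kinds swapped in place). All
guarantees hold in the pre-aligned frame, the screen's default; an align-mode
screen would re-superpose displaced decoys and is not a supported truth-table
condition. Jitter above half the smallest tolerance breaks the active
guarantee and is refused. Every generator is deterministic per seed
(byte-identical outputs).

What the generator does *not* emulate: real chemistry (tautomers,
protonation, conformational strain), docking pose error correlated with
chemistry, and partial/ambiguous feature matches near sphere boundaries.
Passing tests therefore demonstrate the correctness of perception, matching,
acceptance and ranking logic — not virtual-screening enrichment on real
libraries.

## Binding and dose-response analysis

Saturation binding uses `F(c) = F0 + Fmax·c/(Kd + c)`, the model for a FRET
titration of 1 μM dansylated TMEM88 peptide with 2–38 μM PDZ domain
(10-point linear design by default). Competition is handled algebraically:
`Kd_app = Kd(1 + [I]/Ki)` and its inverse `Ki = [I]/(Kd_app/Kd − 1)`; an
apparent Kd at or below the free Kd returns an infinite Ki ("no measurable
inhibition") rather than an error. Treating the observed shift as strictly
competitive is an interpretive choice; the quantities Kd, apparent Kd, Ki
and EC50 are kept distinct and no Cheng–Prusoff conversion is applied
implicitly.

Dose-response uses the four-parameter logistic
`r(d) = bottom + (top − bottom)/(1 + (d/EC50)^hill)` with the default
synthetic design of 8 log-spaced doses spanning 0.01–100× the generating
EC50. Fits use trust-region least squares (scipy) with tight convergence
tolerances (1e-14), initialisation from data (plateaus from the dose
extremes, EC50 from the geometric mean of the half-response bracketing
doses, Hill 1) and bounds EC50 > 0, Hill ∈ [0.1, 10]. Standard errors come
from the covariance (local curvature) of the least-squares objective.
Degenerate inputs fail loudly: constant signal, flat dose dependence, fewer
than 4 distinct concentrations (hyperbola) or 5 distinct doses (4PL).

The inhibition-rate transform is `100·(control − sample)/control` in
percent. A formula sometimes quoted for this assay,
`[control − (sample/control)]·100`, is dimensionally inconsistent and cannot
produce percentage values; the standard normalised form is implemented
instead. Values are not clamped — negative rates mean growth stimulation.

Simulated measurement noise is multiplicative Gaussian (default 2% of
signal) because fluorescence and absorbance errors scale with intensity.

## Problem sizes and numerical choices

Replicated recovery checks use 20 seeds per condition with the designs above
— enough to pin the median within a couple of percent while keeping the full
suite fast. Planted-truth library tests use 16–40 molecules with 3–10
conformers, which already exercises every decoy mode and ranking rule;
screening cost is linear in conformers. Matcher-versus-oracle validation
uses 500 random instances with ≤ 7 queries and ≤ 10 features, the regime
where exhaustive enumeration is itself trustworthy. Assignment ties between
equal-count, equal-RMSD solutions are broken deterministically by the solver
and, in reports, by lexicographic query id.

## Known limitations

- The matcher treats poses as rigid; torsional flexibility must come in as
  extra conformers.
- No excluded volumes, partial charges or directionality: a feature at the
  right distance matches regardless of orientation.
- Align mode's seed-and-extend path is heuristic above the exact-enumeration
  cap; it is exact only on small instances.
- The perception rules are one defensible convention (e.g. hydroxyl oxygens
  count as both donor and acceptor, amide nitrogens as donor only); other
  toolkits draw these lines differently.
- The competitive-shift analysis assumes pure competition; allosteric or
  mixed mechanisms would need a different model.
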