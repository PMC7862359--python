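# Methods

## The register model

The package works on a single-study-year slice of a national cattle
register. Two tables carry everything the analysis needs:

- **animals.csv** — one row per animal: `animal_id`, `herd_id`, `sex`,
  `breed`, `dam_breed`, `sire_breed`, `birth_date`,
  `has_calved_by_sep1`, `herd_entry_date`, `herd_exit_date` (empty =
  still resident). Each animal carries one residency interval in one
  herd; multi-herd histories inside the year are represented through
  the movement table.
- **movements.csv** — one row per movement: `animal_id`, `date`,
  `source_herd`, `destination_id`, `destination_kind`
  (herd / slaughter / export). Slaughter and export are terminal
  destinations, not holdings; marts are not modelled as holdings
  either.

Dates are ISO-8601, files UTF-8 CSV with a header row. Validation
checks date ordering per animal, calved-implies-female, unique animal
ids, known animal on every movement, movement dates inside the study
year, and the three snapshot dates (defaults: Jan 1, May 1, Sep 1 of
the study year, chosen around the seasonal calving pattern).

**Snapshot membership** is half-open: an animal is a member of its herd
on date *t* if `herd_entry_date ≤ t` and (`herd_exit_date` is open or
`> t`). An animal moving on *t* therefore counts only in its
destination herd that day, never in both.

**Breed type** of an animal is derived from its parents: dairy if both
dam and sire breeds are on the six-breed dairy list (Ayrshire, Brown
Swiss, Holstein/Friesian, Jersey, Normande, Norwegian Red), beef if
both are on the 25-breed beef list, cross if one parent is on each
list, and *other* whenever a parent breed is missing or unlisted.
Other-type animals count in herd-size denominators but in no
breed-share numerator; this keeps the proportions well defined without
guessing unknown parentage.

**Birth herd** of an animal is the herd of its first residency: the
source herd of its chronologically first movement of the year, or its
animal-table herd if it never moved. This single-year reconstruction is
what makes the two birth-herd movement variables computable from a
one-year extract: a contract-reared heifer appears as an early out-move
from her birth herd and a late in-move back into it, so the first
movement pins her origin.

## The nine herd variables

| Variable | Quotient | Snapshot / window |
|---|---|---|
| pFemaleAnimals | females / herd size | May |
| pDairyBreed | dairy-bred / herd size | May |
| pCrossBreed | cross-bred / herd size | May |
| pCalvedAnimals | ever-calved / herd size | September |
| pMalesBetween1and2Years | males aged [1,2) y / all animals aged [1,2) y | May |
| pAnimalsLess30Days | purchased animals resold < 30 days later / all out-moves | year |
| pOutMovesToSL | out-moves to slaughter / maximum herd size | year |
| pOutMovesToBirthHerd | out-moves returning an animal to its birth herd / all out-moves | year |
| pInMovesToBirthHerd | in-moves returning an animal to its birth herd / all in-moves | year |

Maximum herd size is the largest of the three snapshot sizes. The age
band [1, 2) years is [365, 730) completed days at the May snapshot,
with no leap-year special-casing. "Resold in under 30 days" uses a
strict inequality: an animal counts if it entered by an inward movement
and left by any outward movement strictly fewer than 30 days later.
Because pOutMovesToSL is normalised by herd size rather than by move
count, it can in principle exceed 1 for extreme finishing herds; values
are passed through unchanged and flagged, never clipped. Any zero
denominator yields 0 with a logged flag, so downstream consumers always
receive complete nine-vectors.

**Initial classification** seeds the typology: herds with
pCalvedAnimals < 0.25 are non-breeding and stay *unknown*; breeding
herds are *dairy* at pDairyBreed ≥ 0.70, *beef* below 0.30, *mixed*
otherwise. Every comparison in the package uses ≥ at its stated
boundary.

## Self-organising maps

The map engine is written from scratch on numpy. Inputs are z-scored
per variable (population 1/K variance; constant variables are rejected
by name). A grid of X×Y weight vectors is initialised uniformly in
[−1, 1] per normalised variable. Each training epoch presents all
records in a fresh seeded permutation; for each record the best
matching unit (BMU) is the node minimising Euclidean distance (ties
break to the first node in row-major order), and every node moves by

    w_xy ← w_xy + α · exp(−d²/(2σ²)) · (z − w_xy),

where *d* is the grid-coordinate Euclidean distance to the BMU. After
each epoch α and σ are multiplied by their decay factors. Defaults:
rectangular grid (no toroidal wrap), α₀ = 0.5, σ₀ = half the larger
grid dimension, both decaying ×0.95 per epoch, 50 epochs. The grid
shape is configuration; nothing in the method fixes it.

**Supervised (bi-directional) training** adds a class-weight grid of
per-node class-membership vectors, initialised near-uniform on the
probability simplex with a small seeded jitter (the jitter breaks the
otherwise total tie in the first BMU searches). At epoch *t* of *T* the
BMU minimises `(1 − t/T)·d²_class + (t/T)·d²_feature`, so the map's
organisation is class-driven early and feature-driven late; both grids
are updated with the same Gaussian neighbourhood. Because every update
is a convex combination with a one-hot vector, class weights stay on
the simplex (renormalised only against floating-point drift). The
argmax class weight labels each node; prediction maps a record to its
feature-space BMU and reads that label. The exact mixing curve is one
concrete realisation of the bidirectional idea; the tests rely only on
the contract that labels steer training early and features refine it.

**Instrumentation.** A component plane is the grid coloured by the
de-normalised weight values of one variable (red high, blue low in the
optional PNG renders). A region histogram is the raw distribution of
one variable over the records whose BMU falls in a chosen node subset.
The walkthrough (`run_walkthrough`) uses both: the "grey region" of a
map is defined empirically as the set of pixels on which the
unclassified herds are represented, which is robust to ties in node
majorities at small training budgets.

## The classification tree

Thirteen decisions (10 binary, 3 ternary), 17 leaves, nine distinct
variables, longest path six decisions:

- **D1** pCalvedAnimals ≥ 0.25 → breeding, else non-breeding.
- Breeding: **D2** (ternary) pDairyBreed ≥ 0.70 → dairy subtree,
  < 0.30 → beef subtree, else leaf **M**.
- Dairy subtree: **D3** male-youngstock share ≥ 0.30 → **DRm**;
  **D4** calved share ≥ 0.60 → **D5**, else **D**;
  **D5** pInMovesToBirthHerd ≥ 0.30 → **DnR-C**, else **DnR-nC**.
- Beef subtree: **D6** pCrossBreed < 0.15 → **BP**;
  **D7** pOutMovesToSL ≥ 0.35 → **BSB**;
  **D8** (ternary) male-youngstock share < 0.20 → **BSW**,
  [0.20, 0.65) → **BSY**, ≥ 0.65 → **BSY-nR**.
- Non-breeding: **D9** pAnimalsLess30Days ≥ 0.50 → **T**;
  **D10** pOutMovesToSL ≥ 0.50 → **F**;
  **D11** pOutMovesToBirthHerd ≥ 0.30 → **Rdf**;
  **D12** pDairyBreed ≥ 0.60 → **Sdm**;
  **D13** (ternary) pFemaleAnimals < 0.35 → **Sbm**, ≥ 0.65 → **Sbf**,
  else **Sbmx**.

The D1, D2, D10 thresholds and the 30-day window inside
pAnimalsLess30Days are fixed conventions of the typology. The remaining
thresholds (D3–D9, D11–D13) are calibration constants chosen midway
between the nominal signatures of the archetypes they separate; they
live in `DEFAULT_THRESHOLDS`, can be overridden programmatically, and
travel with the YAML tree file so domain experts can edit them. D6
tests the cross-bred share alone: within the beef subtree the dairy
share is already low, so a low cross share is what distinguishes
pedigree herds.

**Sensitivity bands.** For a decision node, among the herds whose path
reaches it, each band endpoint is the variable value of the
(⌈f·n⌉+1)-th herd counted outward from the threshold on that side
(f = 0.10 by default): moving the threshold strictly inside the band
reassigns at most ⌈f·n⌉ herds, and ties at equal values cross together.
A side with ⌈f·n⌉ or fewer herds gives an open-ended bound, flagged;
f = 0 degenerates to the threshold itself.

## The synthetic register generator

Real registers cannot be shared, so the generator emits labelled
registers whose herds carry the 17 management signatures. Each
archetype is a vector of nominal fractions — the nine feature targets
plus age-structure and trade-volume knobs (`yearling_fraction`,
`calf_fraction`, `out_rate`, `in_rate`, `short_stay_days`). Herd
composition is built by deterministic rounding of the fractions at the
drawn herd size: sex, breed, age-band and calved counts are exact up to
rounding, and movement counts (slaughter exits, contract legs, dealer
transients, generic trade) are budgeted the same way. Randomness enters
through herd sizes, individual ages, dates, and assignment shuffles;
each herd draws from a deterministic substream of the run seed, so a
fixed configuration reproduces the register byte for byte.

Nominal archetype values (fractions; sizes 60–140 animals except
F 100–200 and T 80–160):

| Type | female | dairy | cross | calved | males 1–2y | short-stay | out→SL | out→birth | in→birth |
|---|---|---|---|---|---|---|---|---|---|
| D      | 0.90 | 0.90 | 0.05 | 0.45 | 0.05 | 0.02 | 0.10 | 0 | 0 |
| DnR-C  | 0.95 | 0.90 | 0.05 | 0.78 | 0.05 | 0.02 | 0.08 | 0 | 0.60 |
| DnR-nC | 0.95 | 0.90 | 0.05 | 0.78 | 0.05 | 0.02 | 0.08 | 0 | 0.05 |
| DRm    | 0.55 | 0.85 | 0.10 | 0.40 | 0.70 | 0.02 | 0.15 | 0 | 0 |
| M      | 0.85 | 0.48 | 0.42 | 0.45 | 0.10 | 0.02 | 0.10 | 0 | 0 |
| BP     | 0.65 | 0.02 | 0.04 | 0.45 | 0.40 | 0.02 | 0.15 | 0 | 0 |
| BSB    | 0.55 | 0.02 | 0.30 | 0.35 | 0.50 | 0.02 | 0.55 | 0 | 0 |
| BSY    | 0.55 | 0.02 | 0.30 | 0.32 | 0.45 | 0.02 | 0.08 | 0 | 0 |
| BSY-nR | 0.40 | 0.02 | 0.30 | 0.28 | 0.85 | 0.02 | 0.08 | 0 | 0 |
| BSW    | 0.70 | 0.02 | 0.30 | 0.45 | 0.05 | 0.02 | 0.08 | 0 | 0 |
| Sdm    | 0.10 | 0.80 | 0.15 | 0.02 | 0.90 | 0.03 | 0.10 | 0.03 | 0 |
| Sbm    | 0.10 | 0.10 | 0.25 | 0.02 | 0.90 | 0.03 | 0.10 | 0.03 | 0 |
| Sbf    | 0.90 | 0.10 | 0.25 | 0.03 | 0.10 | 0.03 | 0.10 | 0.03 | 0 |
| Sbmx   | 0.50 | 0.10 | 0.25 | 0.02 | 0.50 | 0.03 | 0.10 | 0.03 | 0 |
| Rdf    | 0.95 | 0.90 | 0.05 | 0.03 | 0.03 | 0.02 | 0.03 | 0.70 | 0 |
| F      | 0.45 | 0.25 | 0.30 | 0.03 | 0.55 | 0.03 | 0.80 | 0 | 0 |
| T      | 0.50 | 0.30 | 0.30 | 0.05 | 0.50 | 0.80 | 0.05 | 0 | 0 |

These are calibration constants, not field measurements: the herd-type
descriptions fix only qualitative signatures (e.g. fatteners send the
majority of out-moves to slaughter; suckler-to-weanling herds keep
almost no male youngstock), so each nominal value was placed centrally
inside its type's region of the default tree and documented here. The
herd-size ranges are of the order of commercial cattle herds; they were
chosen once, before any recovery statistics were computed, and the
granularity they imply (1/n per count) is the main source of deviation
between nominal and realised features. Fractions smaller than that
granularity are set to exactly 0 rather than to token values that would
always round away.

Mechanically, a herd's May membership is built first (contract-reared
young dairy females arrive in February and return to their birth herd
in November; other members are yearlings, spring-born calves and
adults); exits to slaughter and to trade partners are scheduled in
October–December, after the last snapshot; dealer transients pass
through entirely between the May and September snapshots; and generic
purchases arrive after September 1. Snapshot demographics therefore
stay decoupled from trade volume. Two counterpart herds per primary
herd (`-CP1` trade/contract partner, `-CP2` sales destination) are
emitted with four resident adults each, and labelled `counterpart` so
they never enter recovery statistics.

**What the generator does not emulate** — and hence what passing tests
do not establish about real registers: empirical herd-size
distributions (real ones are heavily right-skewed with many very small
herds), within-year birth and death processes beyond what the features
read, seasonal movement patterns other than the scheduling above,
mixed-management herds lying near decision boundaries, and recording
errors. Label recovery of ~100% on synthetic herds demonstrates
internal consistency of features, archetypes and tree — not real-world
classification accuracy, which the confidentiality of national data
leaves unmeasurable here.

## Behavioural threshold recovery

`herdtyper.calibration` confirms that the printed boundaries are
operative in the assembled pipeline, not just constants in a table: a
one-parameter family of synthetic herds (one archetype fraction varied,
everything else fixed, herd size 400) is classified end-to-end, the
class flip is bisected to 10⁻³, and the boundary is reported as the
discriminating feature value of the first herd on the passing side.
This recovers 0.25 (breeding), 0.70 (dairy), 0.30 (beef) and 0.50
(slaughter) exactly, and a 30-day integer bisection over dealer stay
lengths recovers the dealer window.

## Numerical and design choices

- Population (1/K) variance in the z-scoring; constant variables are an
  error, not silently dropped.
- BMU ties break to the smallest (x, y) in row-major order, making
  training fully deterministic under a fixed seed.
- Weight updates are in place; `0 ≤ α·β ≤ 1` guarantees every node
  moves toward (never past) the presented record.
- The walkthrough's suggested threshold is the centre of the sparsest
  stretch between the two largest histogram modes, not the global
  minimum bin, which would sit at the edge of the empty gap.
- Pipeline defaults (20 herds per type, 12×12 to 14×14 grids, 15–40
  epochs) are sized for the package's own test and demonstration runs;
  all are configuration.
- Zero-denominator features are 0 with a flag rather than missing, so
  maps and tree always receive complete vectors; flagged herds are
  logged at warning level.

## Known limitations

- One residency interval per animal in the animal table; longer
  multi-herd histories must be expressed through movements.
- The exact thresholds of the non-fixed decisions are conventions of
  this implementation; on real data they should be re-derived with the
  map instrumentation and reviewed with domain experts.
- pMalesBetween1and2Years is undefined (flagged 0) in herds with no
  1–2-year-olds; the tree then treats such herds as low-male, which is
  the conservative reading for dairy and store systems.
- Sex-specific sub-typing of fattening herds is deliberately out of
  scope: fattening is an epidemiological dead end for most pathogens.
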