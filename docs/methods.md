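# Methods

This note documents the models, conventions, and design choices behind
each `clcmech` module, and what the synthetic-data generators do and do
not emulate.

## Coordinate and membrane conventions

All coordinates are in Å.  The membrane normal is the z axis and the
extracellular side is +z (the convention in which transporter structures
are drawn extracellular-up); a `MembraneFrame` carries the two leaflet
planes and the sign convention, and every "inside/outside" decision goes
through it.  Trajectory frames are assumed equally spaced; the default
spacing is 0.2 ns (frames saved every 200 ps), so a 1.5 µs production run
corresponds to 7,500 frames.  Analyses default to using every frame.

Periodic boundaries: distances are computed with the minimum-image
convention when an orthorhombic box accompanies a frame.  Wire detection
expects pre-imaged (whole-molecule, protein-centered) trajectories, as
produced by standard re-imaging tools; angle geometry uses the stored
coordinates directly.

## Hydrogen-bond graphs

A hydrogen bond between heavy atoms is defined geometrically: heavy-atom
(donor–acceptor) distance ≤ `d_da_max` (default 3.5 Å) and, when
hydrogens are present, a D–H···A angle at the hydrogen ≥ `angle_min_deg`
(default 150°), with either partner allowed to donate.  These are the
standard water criteria; no published geometry accompanies the wire
observations this package operationalizes, so both parameters are
configuration keys, and wire statistics should always be reported
alongside the criteria used.  A distance-only mode exists for
hydrogen-free (coarse) inputs and is by construction a superset of the
angle-aware graph at equal cutoff.

Candidate pairs come from a KD-tree; the per-pair test is identical to
the naive all-pairs evaluation, so accelerated and brute-force routes
agree exactly (this equivalence is property-tested on random frames).
Edges are stored as sorted `(min_id, max_id)` pairs for deterministic
serialization.  Covalent hydrogens are found per residue within 1.25 Å of
their heavy atom in the analyzed frame.

## Water wires

A wire is a chain of hydrogen-bonded waters linking a *source* (the
gating-glutamate side-chain oxygens in the "out" rotamer, or an
anion-pathway site) to a *sink* (bulk intracellular water, defined as
water oxygens below the inner-leaflet plane).  Search is fewest-hop BFS
on the frame's hydrogen-bond graph with water oxygens as the only relay
nodes — protein side chains may be endpoints but not relays (relaying
through the intracellular glutamate is off by default and switchable).
Among equally short paths the lexicographically smallest node sequence is
returned, implemented by computing hop counts from the sink set and
walking greedily from the source; this makes output deterministic without
affecting the reported length.  There is no default length cap (BFS
terminates); a cap exists for pathological inputs.

Wires are classified into three classes by lining shells: class 1
requires the anion-pathway source; classes 2 and 3 require the
gating-glutamate source and are distinguished by which residue shell
(H⁺-pathway glutamates E202/E203/E113 vs the adjacent interface shell)
has the most wire-water contacts within `contact_radius` (4 Å), ties
breaking to the lower class id and zero contacts giving "unclassified".
The class-2/3 geometric distinction is interpretive — the shells are
shipped defaults and fully configurable, and results should be read
accordingly.

The per-simulation statistic is the fraction of frames with ≥ 1 wire of
any class.  Box summaries across simulations use linear-interpolation
quartiles (a convention choice, documented because none is standard) with
whiskers at the last data points within 1.5× the interquartile range and
points beyond listed as outliers.

## Ion events

The bound/unbound observable is the per-frame minimum distance from the
reference atoms (default: the Y445 hydroxyl oxygen only; configurable to
all side-chain heavy atoms) to any selected Cl⁻.  Smoothing is a centered
moving average; the window in frames is the time window divided by the
frame interval rounded to the nearest integer and then up to odd (20 ns
at 0.2 ns/frame → 101 frames), with shrinking windows at the edges and a
trailing-window mode available.  An unbinding event is an upward crossing
of the smoothed trace through the 12 Å threshold (a raw-trace mode exists
for sensitivity analysis); a run "shows leaving" only when every pathway
ion ends unbound.  Exit direction is the sign of the ion's z displacement
from the pathway-site centroid, read at the first frame the ion exceeds a
15 Å bulk cutoff — deliberately beyond the 12 Å threshold so direction is
read only once the ion is committed; an ion that never reaches bulk is
"indeterminate".  The inner-gate series is the S107 OG–Y445 OH distance
with a default open threshold of 6 Å (interpretive; configurable).

## Map z-scores and RMSD

Map statistics (mean, population SD) are taken over the entire grid by
default — a solvent-masked mode is offered but is not the headline
number.  The z-score at a coordinate is the trilinearly interpolated
density minus the mean, over the SD; nearest-voxel interpolation is
available for sensitivity checks.  A zero-variance map raises a
degenerate-map error rather than returning a value.  Maps are read and
written as MRC/CCP4 through gemmi with axis order normalized on read.

Residue pairing for superposition is chain-aware: chains are matched by
best pairwise sequence-alignment score (recovering shuffled chain ids),
then residues pair by global alignment within matched chains, skipping
indels.  Superposition is a Kabsch least-squares fit with the reflection
corrected to a proper rotation.  Pruning is off for the headline RMSD;
an iterative prune (drop pairs deviating > cutoff, refit until stable,
default 2.0 Å) mirrors how interactive matchmaker tools report values,
and both numbers are always kept because published RMSDs may depend on
unstated pruning settings.

## HDX pH normalization

Intrinsic amide exchange is modelled with the standard three-term form
k_int(pH) = k_A·10^(−pH) + k_B·10^(pH−pKw) + k_W using sequence-averaged
poly-DL-alanine reference constants near the experimental temperature
(~21 °C): log₁₀ k_A = 1.62, log₁₀ k_B = 10.18, log₁₀ k_W = −1.5 (per
minute; converted to s⁻¹ internally) with pK_w = 15.05 for heavy water.
Per-residue sequence dependence is out of scope; only rate *ratios* enter
the pH correction, so the absolute scale cancels.  In the base-dominated
regime the model decreases ~10-fold per pH unit, giving a pH 6.5 → 4.5
correction factor of ≈ 93 (within the "100-fold" working figure) and
matching 20 s at pH 6.5 to ≈ 1.9 × 10³ s at pH 4.5.  Below pH ≈ 3.5 the
acid and water terms bend the curve away from log-linearity — with these
constants the rate minimum falls near pH 3.2 — and correction factors
involving that region are emitted with an "approximate" warning.

Back-exchange correction scales observed deuteration by
(max exchangeable)/(fully deuterated control level), warning when
corrected values exceed the theoretical maximum by > 5%.  Matched-exposure
differencing compares each high-pH timepoint with the chemically
equivalent low-pH exposure (nearest measured timepoint within a factor of
1.5, else log-time interpolation), oriented so positive differences mean
faster-than-chemistry exchange at the lower pH — the signature of a
conformational change rather than chemistry.  Protection factors are fit
as a single-P saturating exponential D(t) = N(1 − e^(−k_int·t/P)) on
back-exchange-corrected curves.

## Flux quantification

Rates are least-squares initial slopes (Theil–Sen optionally, for spiky
electrode traces) over a window (default 10 s) starting at valinomycin
addition, because coupled transport is blocked by the membrane potential
before that.  Chloride slopes convert to mol/s via the extravesicular
volume; pH slopes via a user-supplied buffering capacity
(mol H⁺ · pH⁻¹ · L⁻¹) — the conversion constants and the transporter
count are stated assumptions of the assay, supplied by the user, not
derived quantities.  Sign conventions: Cl⁻ release from vesicles and H⁺
uptake into vesicles are positive.  Because the assay imposes a twofold
outward H⁺ gradient, any leak moves H⁺ out; a negative post-valinomycin
H⁺ slope is therefore reported as leak, never transport, and an H⁺ slope
not exceeding 3 regression standard errors is reported as not measurable,
making the stoichiometry undefined ("n/a") — the behaviour of uncoupled
transporters in this assay.  Replicates aggregate as mean ± SEM, with
stoichiometry aggregated as the mean of per-replicate ratios, which
deliberately differs from the ratio of mean rates on heterogeneous
replicates.

## Synthetic data: what it emulates and what it does not

The generators produce geometric/statistical stand-ins, not physics:

* **Wire fixtures** plant a water chain at the canonical 2.8 Å O–O
  spacing with ideal near-linear hydrogen geometry (each water's first
  hydrogen aimed at the next oxygen), routed through the requested class
  shell; the inner-leaflet plane is derived from the chain so the last
  water is bulk.  The chain is present per frame with the requested
  probability (an unwired frame displaces a mid-chain water beyond the
  cutoff), decoy waters sit in a slab disconnected from the chain, and
  positions get 0.05 Å jitter — an order of magnitude below the bond
  margin, so planted wires are never broken by noise.  Real hydration
  water is disordered and transient; passing these tests shows the
  detection machinery is correct, not that real trajectories contain
  wires.
* **Ion walks** fluctuate 4–6 Å from the reference and then drift
  deterministically at 1 Å/ns past the bulk cutoff in the programmed
  direction.  Real unbinding is diffusive with recrossings; the
  drift-rate choice makes the raw threshold crossing lag the programmed
  exit by ~6 ns, comfortably inside the ± half-window timing tolerance
  the event caller is tested against.
* **Density fixtures** place Gaussian blobs on a Gaussian noise floor.
  The blob center value is set *by construction* to
  mean + z·sd of the realized noise field (blended with a Gaussian
  profile), so the planted z-score is exact up to the blob's (negligible,
  for small blobs on a 64³ grid) effect on whole-map statistics; an
  additive blob would leave ±1 σ of noise at the peak voxel and make
  sub-0.2 recovery checks meaningless.
* **HDX curves** are single-protection-factor saturating exponentials
  scaled by a fully-deuterated efficiency, with additive noise and
  enforced monotonicity.  Real peptides mix per-amide rates and EX1/EX2
  regimes; the generator tests the correction arithmetic, not kinetic
  model selection.
* **Flux traces** are flat-then-linear with Gaussian electrode noise
  (pH noise 1 × 10⁻⁴, chloride 10×, reflecting the clean traces such
  recordings produce), using a 600 µL extravesicular volume and a nominal
  10¹¹ transporters; these magnitudes are plausible assay assumptions,
  not measured constants.

Identical generator arguments (seed included) give bit-identical
fixtures, and the file writers emit the same formats the analysis readers
consume (PDB/DCD, MRC, TSV) with JSON ground-truth sidecars.

## Numerical choices and degenerate inputs

Quartiles: linear interpolation.  H-bond ties: edges sorted by id.  Wire
path ties: lexicographically smallest shortest path.  Classification
ties: lowest class id.  Kabsch: reflection-corrected SVD; degenerate
(rank-deficient) point sets still return a proper rotation, and the RMSD
is rotation-invariant in the degenerate subspace.  Zero-variance maps,
empty ion selections (distinct from "ion far away"), windows preceding
valinomycin, and overlapping wire endpoints all raise typed errors rather
than returning numbers.  Box summaries require ≥ 2 simulations;
superposition requires ≥ 3 pairs.

## Problem sizes in the test suite

The shipped tests and the acceptance script run entirely on generated
data at desk scale: 2,000-frame wire trajectories (~65 waters each),
300 ns ion walks at 0.2 ns/frame, 64³ density grids, and six-replicate
flux panels — sizes chosen so the statistical checks (binomial intervals,
SEM bands) are meaningful while the whole suite runs in well under a
minute per module.  Re-analysis of deposited full-scale trajectories and
maps uses the same code paths unchanged; only the inputs grow.

## Known limitations

The wire class-2/3 distinction is a best-effort reading of depicted
geometry, not ground truth.  The intrinsic-rate model is
sequence-averaged; peptides rich in strongly perturbing side chains will
carry systematic correction error.  Proton hopping itself is not
simulated — wires are a hydration observable, not a transport rate.
Transporter counts in flux assays depend on reconstitution assumptions
the user must supply; absolute turnover numbers inherit that uncertainty
even though stoichiometry (a ratio) largely cancels it.
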