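# Methods

This note documents the models and numerical choices behind pumpgeom, the
defaults that matter, and what the synthetic-data generators do and do not
emulate.

## Structure handling

Structures are flat, ordered lists of atom records from one model of a
PDB/mmCIF file (parsing and PDB writing are delegated to gemmi). Policies:

- **Alternate locations.** One conformer per site is kept: highest
  occupancy, ties broken in favour of altloc `A`. Deterministic and
  standard; the altloc field is retained so the choice is auditable.
- **Author numbering.** All residue selections use author numbering (rabbit
  SERCA1a numbering for the structures this package was written around),
  1-based, ranges inclusive on both ends.
- **Waters and heteroatoms** are parsed and flagged. Selections exclude
  heteroatoms by default, so superpositions never see waters or ligands;
  contact detection can opt back in (water-mediated contacts need water
  oxygens; catalytic geometry needs the nucleotide).
- **Hydrogens** are kept when present (MD frames) and simply absent in
  crystal structures; every operation works in both regimes.
- **Atom pairing** between two structures is strictly key-based on
  (chain, resseq, icode, name). No sequence alignment is attempted: the
  analyses compare conformations of the *same* protein, where key identity
  is the correct equivalence.

"Main chain" means {N, CA, C, O}. Whether a published main-chain RMSD
includes the carbonyl O is rarely stated; the choice is exposed
(`atom_set="mainchain" | "CA" | "all"`) rather than hard-wired.

## Segment registry

Every analysis resolves segment names through a single registry. Three
boundaries are fixed by the structural literature on SERCA and are refused
as overrides (M5M10 = 750–994, P1 = 337–344, L6_7 = 809–830). The A/N/P
domain and M1–M4 helix boundaries are *not* published along with the
per-domain RMSD values they would be needed for; the registry ships
literature-informed defaults (A ≈ 1–43 ∪ 124–235, N ≈ 360–600,
P ≈ 330–359 ∪ 601–739, M1 ≈ 49–73, M2 ≈ 89–124, M3 ≈ 254–273,
M4 ≈ 291–313) and accepts TOML overrides, so per-domain numbers computed
with them are validation guides, not exact reproductions. Composite bodies
(HEADPIECE = A∪N∪P, NP_BODY, NA_BODY, M1M4) are unions of their members and
follow any override.

## Superposition and derived observables

The rigid-body fit is the closed-form Kabsch solution (SVD of the
cross-covariance with the determinant correction excluding reflections).
Degenerate inputs — fewer than 3 points, or a rank-<2 (collinear)
configuration whose rotation about the line is not identifiable — raise
errors rather than returning an arbitrary branch. Optimality is tested
against a random-rotation sampling oracle.

`compare_structures` performs exactly one fit (on the fit segment) and
evaluates every report segment in that frozen frame. This is deliberate:
"segment X deviates by d Å after superposing on Y" is only meaningful
without refitting. Segments that pair no atoms produce per-entry error
records instead of failing the report.

Angle observables are plain three-point angles with the vertex at the
middle-listed residue, measured between Cα atoms unless another atom is
named. The middle-vertex convention is the only reading under which a
sharper helix kink gives a *smaller* "kink angle", matching how the
headpiece (Leu13–Thr86–Leu98) and M1 kink (Trp50–Arg63–Val74) metrics are
used. The Pro337–Pro312 distance is Cα–Cα, the convention used for the
other named distances.

Catalytic geometry: the γ-phosphorus analogue is Pγ for
ATP/AMPPNP/AMPPCP, or the Al atom of an AlF₄⁻/AlF₃ mimic; the aspartate
oxygen Oδ is whichever of OD1/OD2 is closer to it; the reported angle is
Oδ–Pγ–bridge, where the bridge atom is O3B (ATP, or the ADP of an ADP·AlFx
complex) or the methylene carbon C3B of AMPPCP, which chemically replaces
the bridging oxygen of the terminal phosphoanhydride. An in-line associative
geometry approaches 180°.

## Contacts and hydrogen bonds

No single criterion is standard across crystallographic "polar contacts"
and MD hydrogen-bond counts, so two are implemented and the intent is
distribution-level or presence/absence comparison, not exact integers:

- heavy-atom mode (crystal structures, no H): any N/O (S as acceptor) pair
  across the groups within 3.5 Å;
- H-aware mode (MD frames): D–H···A with H···A ≤ 2.5 Å and angle ≥ 120°,
  hydrogens assigned to donors by a 1.25-Å same-residue covalent search;
  each donor–acceptor pair counts once.

Backbone N/O participate (a backbone-N contact is part of the P1–M3
interaction network being tracked). Water-mediated contacts are limited to
single-water bridges with both legs within the heavy-atom cutoff. Neighbor
search uses a k-d tree and is tested against brute-force O(n²) enumeration.

## Trajectory analyses

Trajectories are a topology plus coordinate frames with strictly increasing
times; multi-model PDB is the native format, XTC/DCD load through an
optional MDAnalysis-backed reader. A one-frame trajectory reproduces the
static-structure value of every observable exactly (tested), which ties the
trajectory layer to the geometry layer.

- **Densities**: Gaussian KDE with Silverman bandwidth (default) or a
  fixed-bin histogram rendered as a step function on a fine grid; both are
  normalised to integrate to 1. Fewer than 10 samples is an error.
- **Modes**: local maxima of the density with prominence ≥ 5% of the peak
  (boundary maxima detected by zero-padding). The KDE mode of a flat-topped
  distribution is a noisy estimator — its sampling sd for a standard-normal
  sample at n = 10⁵ is ~0.06 — which the tests account for.
- **Two-state classification** uses a hysteresis band: crossing the high
  threshold is required to enter the high state and vice versa, so noise
  inside the band never flickers. Defaults for the Arg822 in/out analysis
  are low = 10 Å, high = 12 Å, separating the described ~7 Å "in" and
  ~13 Å "out" levels; the partner-atom convention (Cβ vs Cα of residue 340)
  is exposed. As the band width goes to zero the classifier degenerates to
  simple thresholding. Irreversibility means no high→low transition after
  the first low→high.
- **Correlation** is plain Pearson r; **medians** are standard medians. No
  equilibration discard or frame striding is applied by default (both are
  trivial to do on the series).

Not implemented on purpose: PBC re-imaging (frames are assumed whole),
RMSF/PCA, and any helix-axis fitting — the kink metrics are defined as
triplet angles.

## Kinetics and chemistry

**Two-phase association.** F(t) = F₀ + A₁(1−e^(−k₁t)) + A₂(1−e^(−k₂t)),
fitted on points with t ≤ window (default 60 s, matching how such traces
are windowed before the slow drift matters). Double-exponential fits are
initialisation-sensitive, so the solver multi-starts deterministically:
every ordered pair of rates from a fixed log-spaced grid
{0.01, 0.05, 0.2, 1, 5, 10} s⁻¹ seeds a trust-region refinement, with the
amplitudes initialised by linear least squares given the rates (the model
is linear in F₀, A₁, A₂); lowest residual sum of squares wins. Rates are
kept positive by fitting log k. A collapsed fit (rates within 5% or one
amplitude < 0.1% of the total) triggers a single-phase warning.

The half-time t½ is the time at which F reaches F₀ + (A₁+A₂)/2 — the only
parameter-free definition for a two-exponential rise — solved by Brent root
finding; it always lies between ln2/max(k) and ln2/min(k) (tested). On
noiseless model data the fit recovers all five parameters to 1e-6 relative.

**Specific activity.** 1:1 NADH:ATP stoichiometry; activity =
|slope_A340| / (ε·l) / [protein], with ε = 6.22 mM⁻¹cm⁻¹ and l = 1 cm as
assay-standard defaults, yielding µmol ATP·mg⁻¹·min⁻¹. The mutant/WT
activity pair 0.86 / 3.45 gives 24.9% ≈ 25%.

**Ca/EGTA speciation** uses one apparent Kd at fixed pH (user-supplied;
1e-7 M is a reasonable order of magnitude near pH 6.5–7). Free Ca²⁺ is the
positive root of free² + (Kd + EGTA_tot − Ca_tot)·free − Kd·Ca_tot = 0,
computed in the numerically stable form for either sign of the linear
coefficient and verified against an independent mass-balance root finder.
The two regimes of interest behave very differently: with EGTA in excess
the result is strongly Kd-dependent (hence "~100 nM" is treated as
order-of-magnitude only), while with Ca in mM excess over EGTA
(12.609 mM total Ca vs 5 mM EGTA → 7.609 mM free) the Kd decides only the
last fraction of a percent. Multi-proton NIST-constant speciation is out of
scope by design.

## Synthetic data: what it does and does not show

Every generator is seeded (`numpy.random.default_rng`), bit-reproducible,
and emits its ground truth alongside the artifact; the tests consume the
truth records, never hand-copied numbers.

- `make_rigid_pair` — Gaussian point clouds (as Cα-only poly-alanine)
  related by a known rotation/translation plus per-coordinate noise σ. The
  recorded expected post-fit RMSD is √(σ²(3n−6)/n): 3 coordinates per atom
  minus the 6 rigid degrees of freedom absorbed by the fit, noise on one
  copy. Monte-Carlo over 100 seeds agrees within 5%.
- `make_hinged_structure` — two arms with an exact vertex triplet angle
  (error < 1e-9 across a 10°–170° sweep).
- `make_switch_trace` — a step between two levels plus noise; refuses
  levels inside the classifier's hysteresis band (undetectable by
  construction) and records a conservative detection lag (4σ noise margin
  against the threshold).
- `make_bimodal_trace` — Gaussian mixtures; the truth carries a
  mode-recovery tolerance max(0.05, 0.35·σ) reflecting kernel-smoothing
  bias, and flags component overlap within 1σ.
- `make_fluorescence_trace` — the two-phase law sampled at the 2-s
  instrument integration time with Gaussian noise; when a target half-time
  is requested both rates are rescaled by a common factor so the exact
  (root-finding) half-time of the noiseless model equals the target.
- `make_hbond_toy` — donor/acceptor pairs on a 15-Å grid, inside
  (2.8–3.2 Å) or outside (4.5–6.5 Å) the criterion, giving an exact count.

These fixtures validate the *machinery* — estimator correctness, classifier
behaviour, fit recovery — under controlled statistics. They do not emulate
force-field dynamics, solvent, crystallographic disorder, or instrument
drift, so passing them says nothing about whether a particular simulation
or assay would show a given effect; conclusions about the real pump come
from running the same operations on the deposited structures and on real
trajectories and traces.

## Problem sizes

The self-contained checks run at sizes chosen to keep the whole suite
interactive while leaving comfortable statistical margins: rigid-pair
Monte-Carlo at n = 1000 atoms × 100 seeds, switch/mode recovery at 100
seeds (5 000 samples per mixture draw), density oracles at 10⁵ samples,
kinetics ensembles at 20–50 traces of 31 points. The acceptance script uses
50 traces, matching a realistic per-condition experiment count scaled up
for a stable median.

## Known limitations

- Per-domain RMSDs depend on unpublished domain boundaries (see above);
  with the default boundaries they are approximate by construction.
- The heavy-atom contact criterion has no angular term, so crystal-structure
  contact lists can include near-misses a hydrogen-aware criterion would
  reject.
- The catalytic-geometry search assumes one nucleotide analogue per
  structure and raises on ambiguity rather than guessing.
- The two-phase fitter reports, but does not statistically compare,
  per-trace half-times; hypothesis testing across conditions is left to the
  caller.
- Water-mediated contact detection requires ordered waters in the input;
  structures deposited without them will simply report no bridges.
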