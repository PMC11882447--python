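# Methods

This note documents the models, numerical choices and limitations behind
`hydronet`. It covers what each module assumes, which parameters matter and
why their defaults were chosen, and what the synthetic fixtures do and do not
emulate.

## Hydrogen-bond detection

Most deposited membrane-protein structures lack hydrogens, so detection is
defined on heavy atoms. A pair of polar heavy atoms is a hydrogen bond when

* one can donate and the other accept (chemical role table per residue type:
  backbone N donor except proline, backbone O acceptor, side-chain polar
  atoms per residue; water oxygen is both; ligand atoms via a user TSV);
* the heavy-atom distance lies in [2.4, 3.5] Å (defaults);
* for a non-water donor, the angle antecedent–donor–acceptor is ≥ 90°
  ("angle proxy": with no hydrogen present, the acceptor must at least sit in
  the donor's forward hemisphere). Waters rotate freely, so the proxy is
  skipped when the water is the donor; a pair bonds if *any* feasible
  donor/acceptor assignment passes.

These cutoffs are a deliberately simple stand-in for an energy-based
hydrogen-bond term: explicit-solvation forcefields score bonds continuously
and print no single geometric definition, so the criteria here are fully
configurable (`HBondCriteria`) and should be calibrated against
forcefield-scored models when absolute counts matter. Counts are exact and
deterministic for fixed criteria; pairs within one residue are never bonds;
the backbone i→i+4 helical ladder is detected but can be stripped with
`filter_backbone_helical` (it never involves waters, so network statistics
are unaffected either way).

## Network counting rules

The interaction graph has one node per hydrogen-bonding residue and per
water; bonds between the same residue pair collapse into a single edge with a
multiplicity attribute (interactions are counted between nodes, not atom
pairs — a bidentate contact is one interaction).

A **static–switchable water-mediated interaction** is counted per edge: every
residue–water and water–water edge lying on a path

    static residue — water — switchable residue            (2 edges)
    static residue — water — water — switchable residue    (3 edges)

counts exactly once, even when it lies on several such paths. Chains of three
or more waters do not mediate: the extended rule admits exactly one
water–water hop. This per-edge reading makes the single-water case yield one
interaction per hydrogen bond, and it is the reading cross-checked against an
exhaustive path-enumeration oracle in the tests.

`count_water_mediated_total` counts every edge with a water endpoint,
water–water edges included (configurable by filtering edge types before
counting). The 7×7 interface matrix counts, per helix pair, direct
residue–residue edges plus distinct residue pairs bridged through one or two
waters; a pair both directly bonded and water-bridged contributes to both
mechanisms, and intra-helix contacts are excluded.

Consensus solvent nodes: water oxygen positions pooled over the selected
ensemble (by default the 10% lowest-energy models, rounded up, never fewer
than one) are clustered by complete linkage and cut at 1.0 Å; clusters seen
in fewer than 2 distinct models are dropped. The radius matches the scale of
water positional spread between independently repacked models; both knobs are
exposed because "common to multiple models" admits no unique number.

`compare_networks` reports |shared solvated BW codes| divided by the *query*
structure's solvated set (Jaccard available via `denominator="jaccard"`); the
denominator choice is surfaced because the quantity is direction-dependent.

## Ion sampling

The two-stage protocol is fixed by its grids: coarse 0.5 Å spacing over
±2.5 Å (11³ = 1,331 placements) around the site centre, then for each of the
ten best-scoring pose clusters a fine grid of 0.05 Å over ±0.2 Å
(9³ = 729; 7,290 evaluations for ten clusters), pooling the ten best fine
poses. Pose clustering is average-linkage on

    d(p, q) = ‖Δposition‖ + λ·‖Δdistance_vector‖/√L,   λ = 1,

where the distance vector holds the ion's distance to the nearest polar heavy
atom of each declared site residue (L entries); the tree is cut at 1.0 Å and
clusters are ranked by their best member's score (mean-score ranking via
config). Position and contact-signature terms are weighted equally after the
per-dimension √L normalisation since neither is privileged a priori.

Fine grids are centred on each cluster's **best-scoring member** (config
`fine_center`, alternative `"centroid"`). This choice guarantees that every
selected coarse optimum lies inside its refinement grid, hence
min(final) ≤ min(coarse) always holds; centroid centring can place the ±0.2 Å
box entirely away from the optimum when a cluster is spatially extended
(observed 0.14 Å pose errors versus ≤ 0.03 Å with best-member centring).

### Default scorer

The bundled scorer is a documented, deterministic rigid-receptor potential —
it makes no claim to forcefield accuracy and exists so that geometric and
rank-level conclusions can be tested end-to-end; any object with a
deterministic `score(model, position)` can replace it. Terms (constants in
`ScorerParams`):

* screened Coulomb: 332·q_ion·q_i/(ε(r)·r) with distance-dependent
  dielectric ε = 10·r, over atoms within 8 Å; partial charges −0.5 e on
  carboxylate oxygens, −0.4 e on neutral acceptor oxygens, +0.3 e on donor
  nitrogens; r clamped at 0.5 Å so clashes score large-positive but finite;
* soft-sphere repulsion 20·(r₀ − r)² below element-dependent contact radii
  (O 2.25, N 2.45, C 3.0 Å against a Na⁺-sized cation);
* first-shell completion: up to six octahedral water sites at 2.3 Å from the
  ion, each contributing −1.5 REU when no model heavy atom lies within 2.6 Å
  of the site.

The bulk reference enumerates first-shell coordination numbers 0–8 with ideal
octahedral geometry (overflow sites on cube diagonals); water–water
soft-sphere repulsion penalises n > 6, so the optimum is six waters at
−9.0 REU — the physically expected Na⁺ first shell. Occupancy uses
RT = 0.593 kcal/mol (298 K) and κ defaults to 1 kcal/mol per REU; because
occupancy is strictly monotone in κ·ΔE, the occupancy *rank order* of designs
is invariant over any positive κ, which is the level at which conclusions
should be read.

### Oracle

The sampler is validated against an independent brute-force scan: 0.05 Å
spacing over the full ±2.5 Å box followed by 0.01 Å spacing around the
box-wide best point. The default scorer is smooth below 0.05 Å, so this
equals a full 0.01 Å enumeration (501³ points) at a fraction of the cost; the
agreement tolerance (0.05 Å) is one fine-grid spacing.

## Allosteric two-state model

BA = K_R/(1+K_R) with K_R = exp(−ΔG_apo/RT) — a logistic in ΔG_apo.
`quasilinearity_check` samples the curve densely over the energy interval
implied by a BA range and fits a line: over BA ∈ [0.4, 0.6] the fit has
R² > 0.999 (the inflection region), while over [0.01, 0.99] the sigmoid shape
dominates. This is what justifies regressing measured basal activities
directly on computed ΔΔG_apo for receptors whose activities sit mid-range.
Energies in forcefield units are converted by κ (default 1) before RT
arithmetic; Pearson r is invariant to κ, slopes scale by 1/κ. Activities of
exactly 0 or 1 are rejected rather than clipped — they imply infinite ΔG
under the model.

## Design selection

The discard rule requires *both* ΔG_inactive and ΔG_active above the unfold
threshold (default 8 REU): destabilising one state is the design lever of
criterion 1, destabilising both predicts unfolding. Criterion 1 flags
ΔΔG_apo > 5 REU; criterion 2 flags static–switchable connectivity < 18;
both thresholds are typical observed values, not hard physical limits, and
are config-exposed. Ranking is lexicographic — unflagged first, connectivity
descending, ΔΔG_apo ascending, then ion ΔE ascending — because the ion term
is a second-order effect that rarely discriminates where criteria 1–2 do
not; the final design-id tie-break makes the order total and
permutation-invariant.

## Conservation

Per-site frequencies exclude gapped sequences from the denominator (standard
practice; `count_gaps=True` switches). The module assumes the alignment was
already restricted to the receptor family of interest — any similarity
filtering happens upstream and is carried only as provenance metadata.
Column addressing walks the gapped reference row, so generic numbers map
correctly even when the reference carries gaps.

## Synthetic fixtures: what they do and do not show

`make_bundle` builds idealised α-helices (1.5 Å rise, 100° twist, Cα at
2.3 Å from the axis) on a circle of radius ~8–9 Å, alternating up/down, with
backbone N/CA/C/O, Cβ, and serine hydroxyls extending radially; coordinates
carry 0.03 Å jitter to break exact degeneracies. Default 26 residues per
helix gives each static–switchable interface several candidate bridge sites.

`plant_water_network` places water oxygens at exactly 2.8 Å from the bridged
residues' polar tips (single bridge: one water on the perpendicular bisector;
chain: two waters 2.8 Å apart, symmetric about the midpoint), choosing the
perpendicular offset direction that maximises clearance and requiring ≥ 4 Å
to every uninvolved polar atom and previously planted water. After planting,
the production hydrogen-bond detector must reproduce exactly the planted
water edges, otherwise the geometry is rejected — this guard ensures the
*expected counts are analytic*, while the independent check remains the
path-enumeration oracle in the tests.

`plant_ion_site` builds a randomly rotated octahedral cage of six carboxylate
oxygens at 2.15 Å from a known centre (inside the soft-sphere contact radius,
so repulsion curvature makes the centre a true minimum rather than a saddle),
enclosed by an apolar shell at 4.2 Å that keeps the stripped-cage model
subhydrated everywhere in the search box (deleting the coordinating residues
therefore yields ΔE > 0 and occupancy < 0.5). The scan optimum is verified at
generation time to lie within 0.05 Å of the intended centre. This is a
synthetic construct — the chemistry (six independent single-oxygen
carboxylates) is not a natural binding-site geometry; it exists to give the
sampler a sharp, known optimum.

`make_activity_dataset` draws ΔΔG_apo uniformly over [−5, 10] REU for 14
designs and sets BA = 0.35 − 0.02·ΔΔG + N(0, σ), clipped into (0.01, 0.99)
with clip events reported. σ defaults to the closed-form value giving a
population |Pearson r| of 0.91 for a uniform predictor:
σ = |slope|·σ_x·√(1/r² − 1) ≈ 0.0395. The panel size, activity scale and
correlation strength mirror a realistic design-validation campaign.

Passing on these fixtures demonstrates that the counting rules, the sampling
protocol and the statistical machinery are implemented correctly — it does
not demonstrate that the default hydrogen-bond criteria or the simplified
ion potential reproduce any particular experimental structure's counts or
energies. Real-structure work should calibrate `HBondCriteria` against
forcefield-scored models and may swap in a physics-grade scorer behind the
`ScorerContract`.

## Degenerate inputs and tie-breaks

* `select_lowest_fraction` keeps ⌈fraction·N⌉ models, never zero; energy
  ties break by input order.
* Altloc resolution keeps the highest-occupancy conformer; ties break
  alphabetically.
* Pose and cluster orderings carry coordinate-based lexicographic tie-breaks
  so repeated runs are bitwise identical.
* Occupancy exponents are clipped at ±700 before `exp` so extreme ΔE values
  return exactly 0 or 1 instead of overflowing.
* Ranking places designs with missing ion energies after those with values
  at the ion tie-break level.

## Problem sizes

Tests and the acceptance script run on deliberately small instances chosen to
exercise every code path: bundles of 7×26 residues, 3–4 planted bridges per
fixture, 20 randomized recovery fixtures, two planted ion sites with full
coarse/fine sampling (1,331 + 7,290 evaluations each) plus dense-scan
oracles, and 300–1,000 synthetic activity panels of 14 designs.
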