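# Methods

This note documents the models implemented in `qsar3d`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that matter when comparing against other
field-based QSAR implementations.

## Alignment and parameterization

Molecules are treated as rigid bodies. `align_to_template` performs the
Kabsch least-squares superposition over a user-supplied scaffold atom map
(≥ 3 non-collinear pairs; for a furanone series, naturally the five ring
atoms): proper rotation plus translation, no scaling, reflections rejected
via the SVD determinant correction. The transform is estimated on the
mapped pairs only and applied to all atoms; the achieved scaffold RMSD is
returned. Conformational search and force-field minimization are out of
scope — inputs are modeled as provided.

Partial charges are Gasteiger PEOE (iterative partial equalization of
orbital electronegativity, via RDKit). They depend only on the molecular
graph, so they are exactly pose-independent. Van der Waals radii (Bondi)
and Lennard-Jones well depths ship in a versioned per-element table
(`data/vdw_params.json`), together with coarse per-element hydrophobicity
increments. CoMSIA atomic property weights follow the method's original
convention: steric = r³_vdw (Å³), electrostatic = partial charge (e),
hydrophobic = element increment, donor = 1 for O/N bearing a hydrogen,
acceptor = 1 for O and for uncharged N of degree ≤ 3. These rules are
deliberately simple and rule-based; directional (geometry-dependent)
H-bond fields are not implemented.

## Fields

The lattice is the smallest axis-aligned grid at the requested spacing
(default 1.0 Å) covering every atom of every molecule plus a margin
(default 4.0 Å) on all faces.

**CoMFA.** Steric energy at a point is a 6-12 Lennard-Jones sum over atoms
with combination rules R_min = r_atom + r_probe and ε = √(ε_atom·ε_probe);
electrostatic energy is Coulombic, 332.06·q_i·q_probe/(ε(r)·r) kcal·mol⁻¹
with the distance-dependent dielectric ε(r) = r. The probe is a charged sp³
carbon (r 1.70 Å, ε 0.1094 kcal·mol⁻¹, charge +1). Both fields are
truncated at ±cutoff (default 30 kcal·mol⁻¹). Where the steric term hits
the +cutoff plateau the point is inside the molecule and the electrostatic
value is physically meaningless; such entries are replaced by the column
mean over the non-buried molecules (the classic convention), or zero if
every molecule is buried there.

**CoMSIA.** Similarity indices A_F,k(q) = Σᵢ W_probe,k·W_ik·exp(−α·r²_iq)
with attenuation factor α = 0.3 Å⁻² and unit probe weights, summed over all
atoms with no distance cutoff. Values are smooth and bounded, which is the
method's point.

**Column filtering and scaling.** Columns whose value range across
molecules falls below a threshold are dropped (ties kept). The threshold
default is 2.0 kcal·mol⁻¹ for CoMFA; for CoMSIA the pipeline defaults to
0.1 similarity units, because the indices are dimensionless and roughly two
orders of magnitude smaller than probe energies — an energy-scale cut would
empty four of the five similarity fields. Kept columns are centered, never
autoscaled; each field block is weighted by 1/√(total block variance) so no
field dominates through units alone. Contour values and contribution
fractions are invariant to this weighting (|β|·sd products cancel any
per-column rescaling).

## PLS and the statistics suite

PLS is NIPALS with deflation, single response, deterministic initialization
(the score iteration starts from the response), tolerance 1e-12 on the
score-vector change, max 500 iterations (for one response the iteration
converges in a single pass; the guard matters only for future multi-block
use). Coefficients are recovered as B = W(PᵀW)⁻¹C.

* q² (= r²_cv) = 1 − PRESS/Σ(y−ȳ)² from leave-one-out refits, with ȳ the
  mean of the **full** response vector.
* SEP = √(PRESS/(n−c−1)) and SEE = √(SSres/(n−c−1)); the n−c−1 denominator
  is the field's convention for c latent variables plus an intercept.
* F = (r²/c)/((1−r²)/(n−c−1)).
* ONC: scan c = 1..max_comp, locate the SEP minimum, then walk up from one
  component accepting each step only if q² improves by ≥ 10 % — relative
  improvement by default, absolute behind a flag (`relative=False`), since
  the rule's published wording supports either reading. The walk stops at
  the first rejected step. High-signal data saturates this rule early: once
  q² is ~0.9 no step can add 10 %, so ONC lands small by design.
* Bootstrap r²/SEE: molecules resampled with replacement (default 100
  draws), degenerate resamples (constant response / rank collapse) skipped
  and redrawn with the skip count reported.
* Field contributions: Σⱼ|βⱼ|·sd(xⱼ) per field, normalized to 1.

LOO is implemented as literal n refits; there is no shortcut path, and the
test suite still pins it against an independently coded refit loop.

## Progressive scrambling

Molecules are sorted by activity and partitioned into contiguous bins
(default 10); perturbation levels sweep the bin count down to 2 (default 8
levels, 10 scrambles per level), permuting y within bins so the coarse
activity trend survives while fine ordering is destroyed. For each
scrambled response the squared Pearson correlation r²_yy′ with the original
y and the LOO q² (and SDEP = √(PRESS/n)) of a refit model are recorded,
plus the unperturbed model as the (1, q²₀) anchor. Quadratic fits of q² and
SDEP against r²_yy′ are evaluated at the conventional critical point 0.85:
Q² (corrected q²), cSDEP, and the sensitivity slope dq²/dr²_yy′. Slopes
near 1 indicate a stable model; values well above ~1.2 flag models whose
apparent q² rides on response redundancy. All constants are arguments.

## External validation

r²_pred = (SD − PRESS)/SD with SD the squared deviations of test-set
activities from the **training** mean and PRESS the squared
predicted-observed deviations. Residuals are predicted − observed
throughout. Negative r²_pred is reported as-is. An r²_m-style metric is
deliberately not included: the package only ships statistics with an
anchored formula.

## Contours

For a chosen field, each kept lattice point gets coefficient × column
standard deviation (STDEV*COEFF); dropped columns are exactly zero. Favored
points lie strictly above the 80th percentile of the nonzero values,
disfavored strictly below the 20th (both configurable); percentiles over
the nonzero population only, strict inequality, so a constant field yields
empty sets. Scalar fields export as text OpenDX for molecular viewers.

## Synthetic data generator

The generator emulates the *shape* of a published furanone-inhibitor data
set: 52 analogs on a rigid five-membered-ring scaffold (one ring oxygen,
one exocyclic carbonyl oxygen), three substituent sites on the ring
carbons, pIC₅₀ spanning ≥ 2 log units, and a stratified 44/8 train/test
split (test molecules span the activity range, as such studies select
them). Substituents are pseudo-atom spheres (1-3 per group) drawn from an
eight-group library; each group specifies radius and charge **ranges**
realized per molecule, so homologous substituents are similar but not
identical. Activity is baseline 4.2 + 0.12·(substituent volume at site 0)
− 3.0·(substituent charge at site 1) + 0.3·(donor flag at site 1) +
N(0, 0.1) pIC₅₀ — a bulky-favored steric hotspot, an
electronegativity-favored electrostatic effect with a small donor bonus,
and site 2 as an inactive decoy. The 0.1 noise floor loosely matches the
residual scale of a well-behaved published model on a ~2.5-unit range.
Ground truth records the noiseless activities, realized per-site descriptor
values, and the causal region geometry (sphere positions + 3 Å radius) for
contour-recovery scoring.

What this does **not** emulate: real chemistry (no bonds, tautomers,
conformers or synthesizability), alignment noise (molecules are born in the
shared scaffold pose; misalignment is produced explicitly by
`perturb_pose` for testing the superposition step), correlated substituent
effects between sites, and activity cliffs. Passing the recovery panel
therefore demonstrates that the numerical chain is correct and that the
statistics behave as designed — not that the method will perform comparably
on any real series.

## Recovery benchmark and problem sizes

The recovery panel (five seeds, default study conditions) runs CoMSIA on a
2 Å lattice: the generative truth includes an H-bond donor effect, and only
the similarity fields span the full causal property space — CoMFA's
two-field basis cannot represent donor chemistry, and because the steric
factor dominates this design, the 10 % parsimony rule stops CoMFA at 1-3
components, which caps its external predictivity on some splits (CoMFA
panel results are still computed and reported by the acceptance script).
The 2 Å spacing keeps the panel at seconds per seed; spot checks at 1 Å
give the same qualitative picture. Negative controls (permuted responses
and a zero-weight null panel) and the scrambling monotonicity check run at
the same sizes.

## Known limitations

* Donor/acceptor flags are rule-based and undirectional; aromatic nitrogen
  chemistry and charged species are handled crudely.
* The ONC parsimony rule saturates on high-q² data (see above); users can
  inspect the full component table and override.
* Bootstrap statistics refit at fixed ONC; component count uncertainty is
  not propagated.
* MOL2 reading depends on RDKit's MOL2 perception, which is less robust
  than SDF; SDF is the first-class format.
* Progressive scrambling's quadratic response fit can extrapolate poorly
  if the perturbation levels cluster; the raw (r²_yy′, q²) pairs are always
  returned for inspection.
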