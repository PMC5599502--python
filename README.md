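# qsar3d

Field-based 3D-QSAR for congeneric small-molecule series: CoMFA and CoMSIA
molecular interaction fields, NIPALS partial least squares with leave-one-out
cross-validation, progressive-scrambling sensitivity analysis, external
test-set validation and STDEV*COEFF contour extraction — as an open, tested
Python pipeline with a synthetic-data generator that provides exact ground
truth.

## Who this is for

Medicinal and computational chemists who want the classic field-based QSAR
chain (the workflow behind countless CoMFA/CoMSIA papers, traditionally run
in commercial modeling suites) as a scriptable, inspectable library: aligned
structures in, validated PLS model and 3D favored/disfavored maps out.

## The method

Given a series of analogs sharing a rigid scaffold, each molecule is rigidly
superposed onto a template over mapped scaffold atoms (Kabsch least-squares
fit). A common lattice (1 Å spacing, 4 Å margin by default) is laid over the
aligned set and two kinds of descriptor fields are sampled at every point q:

* **CoMFA** — probe-interaction energies for a charged sp³ carbon probe:
  a 6-12 Lennard-Jones steric term and a Coulomb electrostatic term with
  distance-dependent dielectric ε(r)=r, both truncated at ±30 kcal·mol⁻¹.
* **CoMSIA** — Gaussian similarity indices
  A_F,k(q) = Σᵢ W_probe,k · W_ik · exp(−α·r²_iq), α = 0.3 Å⁻², for five
  atomic properties: steric (r³_vdw), electrostatic (partial charge),
  hydrophobic, H-bond donor and acceptor.

Low-information lattice columns (range < 2.0 kcal·mol⁻¹ for CoMFA; < 0.1
similarity units for CoMSIA) are dropped, fields are block-weighted to equal
total variance, and the activity pIC₅₀ = −log₁₀ IC₅₀ [M] is regressed by
NIPALS PLS on centered (not autoscaled) columns. The statistics suite is the
one practitioners report:

* q² = 1 − PRESS/Σ(y−ȳ)² and SEP from leave-one-out cross-validation,
* the optimum number of components (ONC) from the lowest SEP with a
  parsimony rule (extra components accepted only for ≥ 10 % relative q² gain),
* r², SEE = √(SSres/(n−c−1)), F, bootstrap r²/SEE, per-field contribution
  fractions Σ|βⱼ|·sd(xⱼ),
* external r²_pred = (SD − PRESS)/SD over a held-out test set,
* progressive scrambling (Q², cSDEP and the dq²/dr²_yy′ slope at the 0.85
  critical point) as an overfitting alarm,
* STDEV*COEFF contours at the 80th/20th percentiles giving favored and
  disfavored 3D regions per field (exportable as OpenDX).

Because published structure sets of this kind are typically unavailable as
coordinates, the package ships a synthetic generator: ~52 pre-aligned
furanone-like analogs whose activity is constructed from known spatial
steric/electrostatic/H-bond weights plus noise, so every stage of the chain
can be tested against exact ground truth.

## Worked example

```python
import numpy as np
from qsar3d import (SyntheticSpec, generate_set, train_test_split, run_qsar,
                    region_overlap)

spec = SyntheticSpec(seed=1)                     # 52 analogs, 44/8 split
mols, truth = generate_set(spec)
split = train_test_split(mols, spec.n_test, seed=2)
train = [m for m in mols if split[m.id] == "train"]
test  = [m for m in mols if split[m.id] == "test"]

result = run_qsar(train, test, method="comsia", spacing=2.0, seed=1)
print(result.stats)
cs = result.contours["comsia_steric"]
overlap = region_overlap(cs.favored_points[:, :3],
                         truth.causal_regions["site0_steric"])
```

Output:

```
ONC          2
q2 / SEP     0.903 / 0.220
r2 / SEE / F 0.935 / 0.180 / 296.5
boot r2      0.923
r2_pred      0.894
contributions {'steric': 0.284, 'electrostatic': 0.167, 'hydrophobic': 0.234,
               'donor': 0.137, 'acceptor': 0.178}
favored-steric cells 19, overlap with true hotspot 0.84
```

Reading: two latent components suffice (q² 0.90 cross-validated, SEP 0.22
pIC₅₀ units); the final model explains 93.5 % of training variance and
predicts the eight held-out molecules with r²_pred 0.89; and 84 % of the
favored-steric contour cells fall inside the region where the generator
actually placed the bulky-group-favored effect — the map points at the right
place.

A command-line layer mirrors the stages (`qsar3d simulate | align | fields |
fit | scramble | validate | contour`); run `qsar3d --help`.

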