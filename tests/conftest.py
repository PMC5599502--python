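"""Shared fixtures: hand-written V2000 molblocks (deterministic coordinates,
no embedding) and a cached synthetic study panel."""

from __future__ import annotations

import numpy as np
import pytest

from qsar3d import SyntheticSpec, generate_set, run_qsar, train_test_split

# methane: tetrahedral, C at origin
METHANE_MOLBLOCK = """methane
  hand  3D

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6294    0.6294    0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294   -0.6294    0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294    0.6294   -0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6294   -0.6294   -0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
"""

# methanol with explicit hydrogens (hydroxyl O bears an H)
METHANOL_MOLBLOCK = """methanol
  hand  3D

  6  5  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5000    0.9000    0.3000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5000   -0.9000    0.3000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3000    0.0000   -1.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8000    0.8500    0.2000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  2  6  1  0
M  END
"""


@pytest.fixture
def methane_sdf(tmp_path):
    p = tmp_path / "methane.sdf"
    p.write_text(METHANE_MOLBLOCK + "$$$$\n")
    return p


@pytest.fixture
def two_record_sdf(tmp_path):
    p = tmp_path / "pair.sdf"
    p.write_text(METHANE_MOLBLOCK + "$$$$\n" + METHANOL_MOLBLOCK + "$$$$\n")
    return p


@pytest.fixture(scope="session")
def synthetic_study():
    """One default synthetic study (seed 1): molecules, ground truth, split."""
    spec = SyntheticSpec(seed=1)
    mols, gt = generate_set(spec)
    split = train_test_split(mols, spec.n_test, seed=spec.seed + 1)
    train = [m for m in mols if split[m.id] == "train"]
    test = [m for m in mols if split[m.id] == "test"]
    return {"spec": spec, "mols": mols, "gt": gt, "split": split,
            "train": train, "test": test}


@pytest.fixture(scope="session")
def comsia_result(synthetic_study):
    """Fitted CoMSIA pipeline on the seed-1 study at the reduced 2 A grid."""
    return run_qsar(
        synthetic_study["train"],
        synthetic_study["test"],
        method="comsia",
        spacing=2.0,
        seed=1,
        n_bootstrap=0,
    )


@pytest.fixture(scope="session")
def small_matrix(synthetic_study):
    """A modest descriptor matrix for PLS/scrambling tests: CoMSIA on a very
    coarse lattice keeps the column count low and fits fast."""
    from qsar3d import assemble_matrix, build_grid, column_filter, comsia_blocks

    train = synthetic_study["train"]
    y = np.array([m.activity for m in train])
    grid = build_grid(train, spacing=3.0, margin=3.0)
    blocks = comsia_blocks(train, grid)
    filtered, _ = column_filter(blocks, threshold=0.1)
    filtered = {k: b for k, b in filtered.items() if b.values.shape[1] > 0}
    return assemble_matrix(filtered, y)
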