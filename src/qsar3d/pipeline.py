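"""End-to-end 3D-QSAR analysis driver.

Chains the pipeline the way a practitioner runs it: common grid over the
aligned training set, CoMFA and/or CoMSIA field computation, column
filtering, descriptor assembly with block weighting, LOO component scan with
the parsimony rule, final non-cross-validated fit, bootstrap, field
contributions, external test-set prediction and STDEV*COEFF contours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contours import ContourSet, extract_contours, stdev_coeff_field
from .field_engine import (
    GridRegion,
    build_grid,
    column_filter,
    comfa_blocks,
    comsia_blocks,
)
from .molecules import Molecule
from .pls_engine import (
    DescriptorMatrix,
    PLSModel,
    assemble_matrix,
    bootstrap_stats,
    field_contributions,
    fit_pls,
    predict,
    select_onc,
)
from .validation import ValidationReport, r2_pred

__all__ = ["QSARResult", "run_qsar", "compute_blocks"]


@dataclass
class QSARResult:
    """Everything a fitted CoMFA or CoMSIA analysis reports."""

    method: str
    model: PLSModel
    matrix: DescriptorMatrix
    grid: GridRegion
    onc_table: list[dict]
    validation: ValidationReport | None
    test_predictions: pd.Series | None
    contours: dict[str, ContourSet]

    @property
    def stats(self) -> dict[str, float]:
        s = {
            "q2": self.model.q2,
            "sep": self.model.sep,
            "r2": self.model.r2,
            "see": self.model.see,
            "f_stat": self.model.f_stat,
            "onc": self.model.ncomp,
            "boot_r2": self.model.boot_r2,
            "boot_see": self.model.boot_see,
        }
        if self.model.contributions:
            for k, v in self.model.contributions.items():
                s[f"contribution_{k}"] = v
        if self.validation is not None:
            s["r2_pred"] = self.validation.r2_pred
        return s


def compute_blocks(
    mols: Sequence[Molecule],
    grid: GridRegion,
    method: str = "comfa",
    cutoff: float = 30.0,
    alpha: float = 0.3,
    comsia_fields_used: Sequence[str] | None = None,
):
    """Field blocks for one method over a fixed grid."""
    if method == "comfa":
        return comfa_blocks(mols, grid, cutoff=cutoff)
    if method == "comsia":
        from .field_engine import COMSIA_FIELDS

        return comsia_blocks(
            mols, grid, alpha=alpha,
            fields=comsia_fields_used or COMSIA_FIELDS,
        )
    raise ValueError(f"unknown method {method!r}; use 'comfa' or 'comsia'")


def run_qsar(
    train_mols: Sequence[Molecule],
    test_mols: Sequence[Molecule] = (),
    method: str = "comfa",
    spacing: float = 1.0,
    margin: float = 4.0,
    cutoff: float = 30.0,
    alpha: float = 0.3,
    column_threshold: float | None = None,
    max_comp: int = 10,
    n_bootstrap: int = 100,
    seed: int = 0,
    fav_pct: float = 80.0,
    disfav_pct: float = 20.0,
    comsia_fields_used: Sequence[str] | None = None,
) -> QSARResult:
    """Run the full analysis for one method.

    The grid is built over training AND test molecules so external
    predictions sample the same lattice; the column filter and the model see
    only the training rows.

    ``column_threshold`` defaults per method: 2.0 kcal/mol for CoMFA energy
    fields, 0.1 for the dimensionless CoMSIA similarity indices (an energy
    -scale cut would discard nearly all similarity columns).
    """
    if column_threshold is None:
        column_threshold = 2.0 if method == "comfa" else 0.1
    train_mols = list(train_mols)
    test_mols = list(test_mols)
    if any(m.activity is None for m in train_mols):
        raise ValueError("every training molecule needs an activity")
    y = np.array([m.activity for m in train_mols], dtype=float)

    grid = build_grid(train_mols + test_mols, spacing=spacing, margin=margin)
    blocks = compute_blocks(train_mols, grid, method, cutoff, alpha,
                            comsia_fields_used)
    filtered, masks = column_filter(blocks, threshold=column_threshold)
    # fields whose every column was filtered out drop from the model
    filtered = {k: b for k, b in filtered.items() if b.values.shape[1] > 0}
    X = assemble_matrix(filtered, y)

    onc, table = select_onc(X, max_comp=max_comp)
    model = fit_pls(X, None, onc)
    model.q2 = table[onc - 1]["q2"]
    model.sep = table[onc - 1]["sep"]
    model.contributions = field_contributions(model, X)
    if n_bootstrap > 0:
        model.boot_r2, model.boot_see, _ = bootstrap_stats(
            X, None, onc, n_runs=n_bootstrap, seed=seed
        )

    validation = None
    test_pred = None
    if test_mols:
        test_blocks = compute_blocks(test_mols, grid, method, cutoff, alpha,
                                     comsia_fields_used)
        parts = []
        for label in filtered:
            vals = test_blocks[label].values[:, masks[label]]
            parts.append(vals * X.block_scale[label])
        X_test = np.hstack(parts)
        preds = predict(model, X_test)
        test_pred = pd.Series(preds, index=[m.id for m in test_mols])
        obs = np.array([m.activity for m in test_mols], dtype=float)
        if np.all(np.isfinite(obs)):
            validation = r2_pred(obs, preds, float(y.mean()),
                                 ids=[m.id for m in test_mols])

    contour_sets = {}
    for label in filtered:
        fld = stdev_coeff_field(model, X, label, grid)
        contour_sets[label] = extract_contours(fld, grid, fav_pct, disfav_pct,
                                               field_label=label)

    return QSARResult(
        method=method,
        model=model,
        matrix=X,
        grid=grid,
        onc_table=table,
        validation=validation,
        test_predictions=test_pred,
        contours=contour_sets,
    )
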