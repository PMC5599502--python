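"""External test-set validation and residual reporting.

The predictive power of a QSAR model is judged on molecules never seen
during training via

    r^2_pred = (SD - PRESS) / SD

where SD is the sum of squared deviations of the test-set activities from
the TRAINING-set mean activity, and PRESS the sum of squared deviations
between predicted and observed test activities.  r^2_pred is 1 for perfect
prediction, 0 for a model no better than predicting the training mean, and
unbounded below (negative values are reported as-is, never clamped).

Residuals follow the convention residual = predicted - observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ValidationReport", "r2_pred", "residual_table"]


@dataclass
class ValidationReport:
    r2_pred: float
    press: float
    sd: float
    residuals: pd.DataFrame  # columns: observed, predicted, residual

    def __post_init__(self) -> None:
        if self.press < 0 or self.sd <= 0:
            raise ValueError("PRESS must be >= 0 and SD > 0")


def r2_pred(
    test_obs: np.ndarray,
    test_pred: np.ndarray,
    train_mean: float,
    ids: list[str] | None = None,
) -> ValidationReport:
    """External predictive coefficient r^2_pred = (SD - PRESS)/SD.

    ``train_mean`` is the mean activity of the training molecules only.
    """
    obs = np.asarray(test_obs, dtype=float)
    pred = np.asarray(test_pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("observed/predicted vectors must match and be non-empty")
    sd = float(np.sum((obs - train_mean) ** 2))
    if sd == 0:
        raise ValueError("SD is zero: every test observation equals the train mean")
    press = float(np.sum((pred - obs) ** 2))
    resid = pred - obs
    table = pd.DataFrame(
        {"observed": obs, "predicted": pred, "residual": resid},
        index=ids if ids is not None else range(obs.size),
    )
    return ValidationReport(r2_pred=(sd - press) / sd, press=press, sd=sd,
                            residuals=table)


def residual_table(
    observed: pd.Series,
    predictions: dict[str, pd.Series],
    split: pd.Series,
) -> pd.DataFrame:
    """Long-format observed/predicted/residual table.

    Parameters
    ----------
    observed : pIC50 indexed by molecule id.
    predictions : per model label, predicted pIC50 indexed by molecule id;
        every observed molecule must be predicted by every model.
    split : 'train'/'test' labels indexed by molecule id.

    Returns one row per molecule x model with columns
    (molecule_id, model, observed, predicted, residual, split); residual is
    predicted - observed.  Round-trips through CSV at 4 decimals.
    """
    rows = []
    for label, pred in predictions.items():
        missing = [i for i in observed.index if i not in pred.index]
        if missing:
            raise ValueError(f"model {label!r} missing predictions for {missing}")
        for mid in observed.index:
            o = float(observed.loc[mid])
            p = float(pred.loc[mid])
            rows.append(
                {
                    "molecule_id": mid,
                    "model": label,
                    "observed": o,
                    "predicted": p,
                    "residual": p - o,
                    "split": str(split.loc[mid]) if mid in split.index else "train",
                }
            )
    return pd.DataFrame(rows)
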