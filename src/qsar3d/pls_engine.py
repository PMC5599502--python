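"""NIPALS partial least squares with the 3D-QSAR statistics suite.

Field matrices have thousands of collinear columns and only a few dozen
molecules, the classic PLS regime.  Columns are centered but NOT autoscaled
(autoscaling would blow up the near-constant lattice columns); instead each
descriptor block is weighted so that every field contributes equal total
variance before fitting (CoMFA-standard scaling).

The suite mirrors what QSAR practitioners report:

* r^2, SEE, F           — non-cross-validated fit at the chosen components,
                          SEE = sqrt(SSres / (n - ncomp - 1)),
                          F = (r^2/ncomp) / ((1-r^2)/(n-ncomp-1));
* q^2 (r^2_cv), SEP     — leave-one-out cross-validation,
                          q^2 = 1 - PRESS / sum((y - mean(y))^2) with the
                          mean taken over the FULL response vector,
                          SEP = sqrt(PRESS / (n - ncomp - 1));
* ONC                   — optimum number of components: lowest SEP, with a
                          parsimony rule that a higher count is accepted only
                          when q^2 rises by at least 10 % (relative by
                          default) over the previous accepted count;
* bootstrap r^2 / SEE   — resampling molecules with replacement;
* field contributions   — sum_j |coef_j| * sd(X_j) per field, normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .field_engine import FieldBlock

__all__ = [
    "DescriptorMatrix",
    "PLSModel",
    "assemble_matrix",
    "fit_pls",
    "predict",
    "loo_q2",
    "press_q2",
    "select_onc",
    "apply_onc_rule",
    "bootstrap_stats",
    "field_contributions",
]


# ---------------------------------------------------------------------------
# Descriptor matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Stacked (and optionally block-weighted) field descriptors.

    ``block_index`` maps every column to ``(field_label, lattice point id)``;
    ``block_scale`` records the per-field weight applied during assembly so
    coefficients can be mapped back to raw-field units.
    """

    X: np.ndarray
    y: np.ndarray
    block_index: list[tuple[str, int]]
    block_scale: dict[str, float] = dc_field(default_factory=dict)
    molecule_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match y length")
        if len(self.block_index) != self.X.shape[1]:
            raise ValueError("block_index must cover every column")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in descriptor matrix")

    def columns_of(self, field_label: str) -> np.ndarray:
        return np.array(
            [j for j, (lab, _) in enumerate(self.block_index) if lab == field_label],
            dtype=int,
        )

    @property
    def field_labels(self) -> list[str]:
        seen: list[str] = []
        for lab, _ in self.block_index:
            if lab not in seen:
                seen.append(lab)
        return seen


def assemble_matrix(
    blocks: Mapping[str, FieldBlock],
    y: np.ndarray,
    block_weighting: bool = True,
) -> DescriptorMatrix:
    """Stack filtered FieldBlocks into one X matrix.

    With ``block_weighting`` (default) each field is scaled by
    1/sqrt(total column variance of the field) so no single field dominates
    the covariance purely through its units — the CoMFA-standard treatment.
    """
    y = np.asarray(y, dtype=float)
    parts = []
    index: list[tuple[str, int]] = []
    scales: dict[str, float] = {}
    mol_ids: tuple[str, ...] = ()
    for label, block in blocks.items():
        if block.values.shape[0] != y.size:
            raise ValueError(f"block {label} row count does not match y")
        mol_ids = block.molecule_ids
        vals = block.values
        if block_weighting:
            total_var = float(vals.var(axis=0, ddof=1).sum())
            scale = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
        else:
            scale = 1.0
        scales[label] = scale
        parts.append(vals * scale)
        index.extend((label, int(p)) for p in block.point_ids)
    if not parts:
        raise ValueError("no field blocks supplied")
    return DescriptorMatrix(
        np.hstack(parts), y, index, scales, molecule_ids=mol_ids
    )


# ---------------------------------------------------------------------------
# NIPALS PLS (single response)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted PLS model plus the statistics suite.

    Coefficients live in the (column-centered) descriptor space the model was
    fit in; ``predict`` applies centering internally.  Cross-validated
    statistics (q2, sep) and bootstrap/contribution summaries are attached by
    the higher-level drivers and default to None until computed.
    """

    ncomp: int
    coefficients: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    r2: float
    see: float
    f_stat: float
    fitted: np.ndarray
    q2: float | None = None
    sep: float | None = None
    contributions: dict[str, float] | None = None
    boot_r2: float | None = None
    boot_see: float | None = None
    block_index: list[tuple[str, int]] | None = None

    def coefficients_full(self, n_points: int, field_label: str) -> np.ndarray:
        """Coefficients of one field expanded onto the full lattice (zeros at
        filtered-out columns).  Requires ``block_index``."""
        if self.block_index is None:
            raise ValueError("model carries no block index")
        out = np.zeros(n_points)
        for j, (lab, p) in enumerate(self.block_index):
            if lab == field_label:
                out[p] = self.coefficients[j]
        return out


def _nipals(Xc: np.ndarray, yc: np.ndarray, ncomp: int, tol: float = 1e-12,
            max_iter: int = 500) -> np.ndarray:
    """NIPALS latent decomposition on centered data; returns the regression
    coefficient vector mapping centered X to centered y.

    Deterministic initialization: the score iteration starts from the
    response (the highest-variance candidate for a single-column Y block),
    which for PLS1 converges in one pass; the loop still guards with a
    tolerance on the score-vector change.
    """
    n, p = Xc.shape
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    C = np.zeros(ncomp)
    X = Xc.copy()
    y = yc.copy().astype(float)
    for a in range(ncomp):
        u = y.copy()
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm < 1e-300:
                raise np.linalg.LinAlgError(
                    f"NIPALS found no remaining covariance at component {a + 1}"
                )
            w /= norm
            t = X @ w
            c = float(t @ y) / float(t @ t)
            u_new = y * c  # single-response inner mapping
            if t_old is not None and np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
            u = u_new
        tt = float(t @ t)
        p_load = X.T @ t / tt
        W[:, a] = w
        P[:, a] = p_load
        C[a] = float(t @ y) / tt
        X = X - np.outer(t, p_load)
        y = y - t * C[a]
    # B = W (P'W)^-1 C
    return W @ np.linalg.solve(P.T @ W, C)


def fit_pls(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLSModel:
    """Fit a PLS model on column-centered data (no autoscaling).

    Accepts a plain (X, y) pair or a :class:`DescriptorMatrix` as first
    argument (in which case ``y`` may be None).
    """
    block_index = None
    if isinstance(X, DescriptorMatrix):
        block_index = X.block_index
        if y is None:
            y = X.y
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 molecules to fit")
    if np.allclose(y, y[0]):
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    max_rank = int(np.linalg.matrix_rank(Xc))
    if not 1 <= ncomp <= min(max_rank, n - 1):
        raise ValueError(
            f"ncomp={ncomp} outside valid range 1..{min(max_rank, n - 1)}"
        )
    coef = _nipals(Xc, yc, ncomp)
    fitted = Xc @ coef + y_mean
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2 = 1.0 - ss_res / ss_tot
    dof = n - ncomp - 1
    see = float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan")
    f_stat = (
        (r2 / ncomp) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1.0 else float("inf")
    )
    return PLSModel(
        ncomp=ncomp,
        coefficients=coef,
        intercept=y_mean - float(x_mean @ coef),
        x_mean=x_mean,
        y_mean=y_mean,
        r2=r2,
        see=see,
        f_stat=f_stat,
        fitted=fitted,
        block_index=block_index,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - model.x_mean) @ model.coefficients + model.y_mean


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def press_q2(y_obs: np.ndarray, y_pred: np.ndarray, y_mean: float | None = None
             ) -> tuple[float, float]:
    """(q2, PRESS) from observed/predicted vectors:
    q2 = 1 - sum((obs - pred)^2) / sum((obs - mean)^2)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_mean is None:
        y_mean = float(y_obs.mean())
    press = float(np.sum((y_obs - y_pred) ** 2))
    ss_tot = float(np.sum((y_obs - y_mean) ** 2))
    return 1.0 - press / ss_tot, press


def loo_q2(X: np.ndarray, y: np.ndarray, ncomp: int) -> tuple[float, float]:
    """Leave-one-out cross-validation: refit on n-1 molecules, predict the
    held-out one; returns (q2, SEP) with SEP = sqrt(PRESS/(n - ncomp - 1))
    and the q2 reference mean taken over the full response."""
    if isinstance(X, DescriptorMatrix):
        if y is None:
            y = X.y
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 molecules for LOO")
    preds = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        m = fit_pls(X[keep], y[keep], ncomp)
        preds[i] = predict(m, X[i : i + 1])[0]
    q2, press = press_q2(y, preds, float(y.mean()))
    dof = n - ncomp - 1
    sep = float(np.sqrt(press / dof)) if dof > 0 else float("nan")
    return q2, sep


def apply_onc_rule(
    q2s: Sequence[float], seps: Sequence[float], rel_threshold: float = 0.10,
    relative: bool = True,
) -> int:
    """Parsimony rule for the optimum component count.

    Baseline candidate = argmin SEP; walking up from 1 component, each extra
    component is accepted only when its q2 improves on the previously
    accepted value by at least ``rel_threshold`` (relative by default,
    absolute when ``relative=False``).  Returns the 1-based ONC.
    """
    q2s = list(q2s)
    seps = list(seps)
    best_by_sep = int(np.argmin(seps)) + 1
    onc = 1
    for c in range(2, best_by_sep + 1):
        prev, cur = q2s[onc - 1], q2s[c - 1]
        if relative:
            gain_ok = (
                cur - prev >= rel_threshold * abs(prev) if prev != 0 else cur > 0
            )
        else:
            gain_ok = cur - prev >= rel_threshold
        if gain_ok:
            onc = c
        else:
            break
    return onc


def select_onc(
    X: np.ndarray,
    y: np.ndarray | None = None,
    max_comp: int = 10,
    rel_threshold: float = 0.10,
    relative: bool = True,
) -> tuple[int, list[dict]]:
    """LOO-scan component counts 1..max_comp and apply the parsimony rule.

    Returns (onc, table) where the table has one row per component count with
    its q2 and SEP.
    """
    if isinstance(X, DescriptorMatrix):
        if y is None:
            y = X.y
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    # each LOO fold drops a row; stay within the fold's rank bound
    hi = max(1, min(max_comp, rank - 1, n - 2))
    table = []
    for c in range(1, hi + 1):
        q2, sep = loo_q2(X, y, c)
        table.append({"ncomp": c, "q2": q2, "sep": sep})
    onc = apply_onc_rule([r["q2"] for r in table], [r["sep"] for r in table],
                         rel_threshold, relative)
    return onc, table


# ---------------------------------------------------------------------------
# Bootstrap and field contributions
# ---------------------------------------------------------------------------

def bootstrap_stats(
    X: np.ndarray,
    y: np.ndarray,
    ncomp: int,
    n_runs: int = 100,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Mean r2 and SEE over ``n_runs`` bootstrap resamples of the molecules.

    Degenerate resamples (constant response or insufficient rank) are skipped
    and redrawn; the count of skips is returned for logging.
    """
    if isinstance(X, DescriptorMatrix):
        if y is None:
            y = X.y
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    n = y.size
    r2s, sees = [], []
    skipped = 0
    while len(r2s) < n_runs:
        idx = rng.integers(0, n, size=n)
        try:
            m = fit_pls(X[idx], y[idx], ncomp)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            if skipped > 50 * n_runs:
                raise RuntimeError("bootstrap: too many degenerate resamples")
            continue
        r2s.append(m.r2)
        sees.append(m.see)
    return float(np.mean(r2s)), float(np.mean(sees)), skipped


def field_contributions(model: PLSModel, X: DescriptorMatrix) -> dict[str, float]:
    """Fractional contribution of each field:
    contribution(F) = sum_{j in F} |coef_j| * sd(X_j), normalized to 1.

    Invariant under per-column rescaling (coef scales inversely to sd).
    """
    sds = X.X.std(axis=0, ddof=1)
    mass = np.abs(model.coefficients) * sds
    total = float(mass.sum())
    if total == 0:
        raise ValueError("all coefficients are zero; contributions undefined")
    out: dict[str, float] = {}
    for label in X.field_labels:
        cols = X.columns_of(label)
        out[label] = float(mass[cols].sum()) / total
    return out
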