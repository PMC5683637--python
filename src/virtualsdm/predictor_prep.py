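"""Collinearity screening (VIF) and per-occurrence feature extraction.

The variance inflation factor of predictor j is 1 / (1 − R²_j), with R²_j
from the least-squares regression of layer j on all other layers over the
jointly valid cells.  :func:`vifstep` iteratively drops the worst layer until
every surviving VIF is at or below the threshold (10 by convention).  For
large grids both routines work on a fixed, seeded subsample of cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateLayerError, ParameterError
from .raster import EnvStack

__all__ = ["vif", "vifstep", "extract_features"]

_R2_EPS = 1e-12


def _stack_matrix(stack: EnvStack, max_cells: int, seed: int) -> np.ndarray:
    X = stack.table()
    if len(X) < len(stack) + 2:
        raise ParameterError("too few valid cells for a VIF regression")
    if len(X) > max_cells:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=max_cells, replace=False)]
    sd = X.std(axis=0)
    for j, name in enumerate(stack.names):
        if sd[j] <= 0:
            raise DegenerateLayerError(f"layer {name!r} is constant")
    return (X - X.mean(axis=0)) / sd


def _vif_from_matrix(Z: np.ndarray) -> np.ndarray:
    n, p = Z.shape
    out = np.empty(p)
    for j in range(p):
        others = np.delete(Z, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, Z[:, j], rcond=None)
        resid = Z[:, j] - others @ coef
        r2 = 1.0 - resid @ resid / n  # columns are standardised: SStot = n
        out[j] = np.inf if 1.0 - r2 < _R2_EPS else 1.0 / (1.0 - r2)
    return out


def vif(stack: EnvStack, max_cells: int = 50_000, seed: int = 0) -> pd.Series:
    """Per-layer variance inflation factors (∞ under perfect collinearity)."""
    if len(stack) < 2:
        raise ParameterError("VIF needs at least two layers")
    Z = _stack_matrix(stack, max_cells, seed)
    return pd.Series(_vif_from_matrix(Z), index=stack.names, name="vif")


def vifstep(
    stack: EnvStack,
    threshold: float = 10.0,
    max_cells: int = 50_000,
    seed: int = 0,
) -> tuple[EnvStack, pd.DataFrame]:
    """Iteratively drop the highest-VIF layer until all VIF ≤ threshold.

    Ties on the maximum are broken toward the earliest layer in stack order.
    Returns the surviving stack and a removal log
    (columns: iteration, removed_layer, vif_at_removal).
    """
    Z = _stack_matrix(stack, max_cells, seed)
    names = list(stack.names)
    keep = list(range(len(names)))
    log_rows = []
    iteration = 0
    while len(keep) >= 2:
        vifs = _vif_from_matrix(Z[:, keep])
        worst = int(np.argmax(vifs))  # argmax takes the first of tied maxima
        if vifs[worst] <= threshold:
            break
        iteration += 1
        log_rows.append(
            {
                "iteration": iteration,
                "removed_layer": names[keep[worst]],
                "vif_at_removal": float(vifs[worst]),
            }
        )
        del keep[worst]
    reduced = stack.subset([names[i] for i in keep])
    log = pd.DataFrame(log_rows, columns=["iteration", "removed_layer", "vif_at_removal"])
    return reduced, log


def extract_features(
    stack: EnvStack,
    points: np.ndarray,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature table: one row per point, one column per layer.

    Each row holds the layer values of the cell containing the point.  Rows
    hitting a nodata cell are dropped with a warning.  An optional ``label``
    column (1 presence, 0 background/absence) is attached when given; the
    original point index is preserved in the frame's index.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array of x, y")
    rows, cols = stack.spec.cell_of(points[:, 0], points[:, 1])
    data = {name: stack[name].values[rows, cols] for name in stack.names}
    df = pd.DataFrame(data)
    if labels is not None:
        if len(labels) != len(df):
            raise ParameterError("labels length must match points")
        df["label"] = np.asarray(labels)
    ok = df[stack.names].notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} point(s) falling in nodata cells",
            stacklevel=2,
        )
        df = df[ok]
    return df
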