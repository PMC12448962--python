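"""Dose-volume indices and absolute dose-error comparison between contours.

Indices follow ICRU 83 conventions: D95 and D98 are near-minimum coverage
doses (the minimum dose received by 95% / 98% of the structure), Dmean the
arithmetic mean, D2 the near-maximum dose to the hottest 2%.  The exact rank
convention used here is Dx = the value at rank ceil(x/100 * N) of the
structure's voxel doses sorted descending, i.e. the largest dose d such that
at least x% of voxels receive >= d; an interpolated DVH variant is available
via ``interpolate=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import Volume

__all__ = ["DoseIndices", "DoseErrors", "dvh_index", "dose_indices", "dose_errors", "dose_error_table"]

_INDEX_LEVELS = (95.0, 98.0, "mean", 2.0)


@dataclass(frozen=True)
class DoseIndices:
    """The four reported DVH indices of one contour on one dose grid (Gy)."""

    d95: float
    d98: float
    dmean: float
    d2: float


@dataclass(frozen=True)
class DoseErrors:
    """Absolute index differences |Dx_method - Dx_reference| (Gy)."""

    delta_d95: float
    delta_d98: float
    delta_dmean: float
    delta_d2: float


def dvh_index(
    dose: Volume | np.ndarray,
    mask: np.ndarray,
    x: float | str,
    interpolate: bool = False,
) -> float:
    """Dx in Gy for the voxels selected by ``mask``; ``x="mean"`` for Dmean."""
    dose_vals = dose.values if isinstance(dose, Volume) else np.asarray(dose)
    mask = np.asarray(mask).astype(bool)
    if dose_vals.shape != mask.shape:
        raise ValueError(f"dose shape {dose_vals.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ValueError("empty mask: DVH indices undefined")
    selected = dose_vals[mask].astype(np.float64)
    if isinstance(x, str):
        if x != "mean":
            raise ValueError(f"x must be a percentage in (0, 100] or 'mean', got {x!r}")
        return float(selected.mean())
    if not 0.0 < x <= 100.0:
        raise ValueError(f"x must lie in (0, 100], got {x}")
    desc = np.sort(selected)[::-1]
    if interpolate:
        return float(np.quantile(selected, 1.0 - x / 100.0, method="linear"))
    rank = math.ceil(x / 100.0 * desc.size)
    return float(desc[rank - 1])


def dose_indices(dose: Volume | np.ndarray, mask: np.ndarray, **kw) -> DoseIndices:
    return DoseIndices(
        d95=dvh_index(dose, mask, 95.0, **kw),
        d98=dvh_index(dose, mask, 98.0, **kw),
        dmean=dvh_index(dose, mask, "mean", **kw),
        d2=dvh_index(dose, mask, 2.0, **kw),
    )


def dose_errors(
    dose: Volume | np.ndarray,
    method_mask: np.ndarray,
    physician_mask: np.ndarray,
    **kw,
) -> DoseErrors:
    """|ΔDx| = |Dx(method contour) - Dx(reference contour)| on one dose grid."""
    m = dose_indices(dose, method_mask, **kw)
    r = dose_indices(dose, physician_mask, **kw)
    return DoseErrors(
        delta_d95=abs(m.d95 - r.d95),
        delta_d98=abs(m.d98 - r.d98),
        delta_dmean=abs(m.dmean - r.dmean),
        delta_d2=abs(m.d2 - r.d2),
    )


def dose_error_table(errors: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-fraction dose errors as mean ± SD per (fraction, method).

    ``errors`` must be tidy with columns: patient, fraction, method,
    delta_d95, delta_d98, delta_dmean, delta_d2 (one row per patient ×
    fraction × method).  Returns one row per (fraction, method) with
    ``<index>_mean`` and ``<index>_sd`` columns.
    """
    required = {"patient", "fraction", "method", "delta_d95", "delta_d98", "delta_dmean", "delta_d2"}
    missing = required - set(errors.columns)
    if missing:
        raise ValueError(f"dose-error table missing columns: {sorted(missing)}")
    value_cols = ["delta_d95", "delta_d98", "delta_dmean", "delta_d2"]
    grouped = errors.groupby(["fraction", "method"], sort=True)[value_cols]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{col}_{stat}" for col, stat in out.columns]
    return out.reset_index()
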