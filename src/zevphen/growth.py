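"""Growth curves and area-under-growth-curve (AUGC) matrices.

Replicate colonies of a strain are pooled per (strain, medium, dose),
LOESS-smoothed over time, and integrated by the trapezoid rule over the
common time window.  AUGC integrates the three aspects of colony
population dynamics (lag, rate, capacity) without committing to a
parametric growth model.  Values are scaled to a reference strain so
profiles are comparable across doses and plates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["GrowthCurve", "AUGCMatrix", "build_curves", "compute_augc_matrix", "augc"]


@dataclass
class GrowthCurve:
    """Pooled, smoothed growth curve for one (strain, medium, dose)."""

    strain_id: str
    medium: str
    dose_nM: float
    times: np.ndarray          # unique sorted timepoints
    sizes: np.ndarray          # mean raw size per timepoint
    smoothed: np.ndarray       # LOESS fit on the same grid, clipped at 0
    n_replicates: int
    smoothable: bool = True

    def validate(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.sizes < 0) or np.any(self.smoothed < 0):
            raise ValueError("sizes must be nonnegative")
        if len(self.smoothed) != len(self.times):
            raise ValueError("smoothed values must share the time grid")


@dataclass
class AUGCMatrix:
    """Strains x doses AUGC values with replicate counts and scaling metadata."""

    values: pd.DataFrame   # index strain_id, columns dose_nM
    counts: pd.DataFrame   # replicate colonies per cell
    metadata: dict = field(default_factory=dict)


def build_curves(
    sizes: pd.DataFrame,
    span: float = 0.3,
    size_column: str = "normalized_size",
) -> list[GrowthCurve]:
    """Assemble per-colony size tables over timepoints into smoothed curves.

    Replicates are pooled per (strain, medium, dose) before smoothing; the
    LOESS span is the fraction of pooled points in each local fit (0.3 by
    default: wide spans bias the fit at the knee of saturating curves).  Groups
    with fewer than three distinct timepoints are flagged unsmoothable and
    keep their raw per-timepoint means.  Input row order is irrelevant.
    """
    df = sizes.dropna(subset=[size_column])
    curves = []
    for (strain, medium, dose), g in df.groupby(
        ["strain_id", "medium", "dose_nM"], sort=True
    ):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(dtype=float)
        y = g[size_column].to_numpy(dtype=float)
        grid = np.unique(t)
        means = g.groupby("time_h")[size_column].mean().to_numpy()
        n_rep = int(g.groupby("time_h").size().max())
        if len(grid) < 3:
            curves.append(
                GrowthCurve(strain, medium, dose, grid, means,
                            np.clip(means, 0, None), n_rep, smoothable=False)
            )
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            # all-zero curves make the local weight sums vanish; the fit is
            # still the correct constant
            fitted = lowess(y, t, frac=span)  # sorted (x, yhat) at the data points
        fx, inv = np.unique(fitted[:, 0], return_inverse=True)
        fy = np.zeros_like(fx)
        np.add.at(fy, inv, fitted[:, 1])
        fy /= np.bincount(inv)
        if not np.all(np.isfinite(fy)):
            # degenerate local fits (vanishing weights) fall back to the mean
            fy = np.where(np.isfinite(fy), fy, np.interp(fx, grid, means))
        sm = np.clip(np.interp(grid, fx, fy), 0.0, None)
        curves.append(GrowthCurve(strain, medium, dose, grid, means, sm, n_rep))
    return curves


def augc(times: np.ndarray, sizes: np.ndarray) -> float:
    """Trapezoidal area under a growth curve."""
    return float(np.trapezoid(sizes, times))


def compute_augc_matrix(
    curves: list[GrowthCurve],
    reference_strain: str,
    medium: str | None = None,
) -> AUGCMatrix:
    """Integrate smoothed curves and scale by the reference strain per dose.

    All curves are truncated to the intersection of their time windows
    before integration.  Each strain's AUGC is divided by the reference
    strain's AUGC at the same dose (and medium); if the reference is
    missing for a dose, the median AUGC across strains is used instead,
    with a warning.
    """
    if medium is not None:
        curves = [c for c in curves if c.medium == medium]
    if not curves:
        raise ValueError("no curves to integrate")
    t_lo = max(c.times[0] for c in curves)
    t_hi = min(c.times[-1] for c in curves)
    if t_hi <= t_lo:
        raise ValueError("curves share no common time window")

    rows = []
    for c in curves:
        keep = (c.times >= t_lo) & (c.times <= t_hi)
        rows.append(
            {
                "strain_id": c.strain_id,
                "medium": c.medium,
                "dose_nM": c.dose_nM,
                "augc": augc(c.times[keep], c.smoothed[keep]),
                "n": c.n_replicates,
            }
        )
    df = pd.DataFrame(rows)
    out_frames, count_frames = [], []
    meta: dict = {
        "reference_strain": reference_strain,
        "window": (float(t_lo), float(t_hi)),
        "scaling": {},
    }
    for med, g in df.groupby("medium"):
        raw = g.pivot_table(index="strain_id", columns="dose_nM", values="augc")
        counts = g.pivot_table(index="strain_id", columns="dose_nM", values="n")
        if reference_strain in raw.index:
            ref = raw.loc[reference_strain]
        else:
            warnings.warn(
                f"reference strain {reference_strain!r} missing in medium {med}; "
                "falling back to per-dose median AUGC",
                stacklevel=2,
            )
            ref = raw.median(axis=0)
        ref = ref.where(ref > 0, 1.0)
        meta["scaling"][med] = {float(d): float(v) for d, v in ref.items()}
        scaled = raw.div(ref, axis=1)
        scaled.insert(0, "medium", med)
        counts.insert(0, "medium", med)
        out_frames.append(scaled)
        count_frames.append(counts)
    values = pd.concat(out_frames)
    counts = pd.concat(count_frames)
    if values["medium"].nunique() == 1:
        values = values.drop(columns="medium")
        counts = counts.drop(columns="medium")
    return AUGCMatrix(values=values, counts=counts, metadata=meta)
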