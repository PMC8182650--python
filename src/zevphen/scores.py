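"""Per-strain phenotype scores for inducible-promoter collections.

Implements the screen's bespoke statistics:

* **Aux score** — ratio-of-ratios comparing the growth benefit of induction
  on minimal (YNB) vs complete (SC) medium;
  ``score = (G_M1/G_M0) / (G_R1/G_R0)``.  Auxotroph-like strains score > 1.
* **Toxicity caller** — growth at 100 nM regressed on growth at 0 nM after
  trimming extremes; strains far below the diagonal after correction are
  toxic.
* **Reversibility classes** — ratio of growth without vs with inducer,
  cut at 0.55 and 0.75.
* **Dependence classes** — how much of maximal growth is retained at 0 nM.
* **SDL caller** — log2 colony-size ratio (induced / uninduced) called in
  every replicate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ScoreConfig

__all__ = [
    "aux_scores",
    "toxicity_call",
    "classify_reversibility",
    "classify_dependence",
    "sdl_call",
]


def aux_scores(
    growth: pd.DataFrame,
    pseudogrowth: float = 1e-3,
) -> pd.DataFrame:
    """Rank strains by the auxotrophy score.

    ``growth`` columns: strain_id, G_M0, G_M1, G_R0, G_R1 — total growth on
    YNB (M) and SC (R) at 0 and 1 nM inducer.  Nonpositive totals are
    floored to ``pseudogrowth`` and flagged; strains with missing totals are
    omitted with a warning.  The score is invariant to any per-strain global
    rescaling of growth.
    """
    need = ["G_M0", "G_M1", "G_R0", "G_R1"]
    df = growth.copy()
    missing = df[need].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} strain(s) missing a growth total; omitted",
            stacklevel=2,
        )
        df = df[~missing]
    floored = (df[need] <= 0).any(axis=1)
    vals = df[need].clip(lower=pseudogrowth)
    score = (vals["G_M1"] / vals["G_M0"]) / (vals["G_R1"] / vals["G_R0"])
    out = df[["strain_id"]].copy()
    out[need] = vals
    out["aux_score"] = score
    out["floored_flag"] = floored.to_numpy()
    return out.sort_values("aux_score", ascending=False).reset_index(drop=True)


def toxicity_call(
    x: pd.Series,
    y: pd.Series,
    trim_top: float = 0.02,
    trim_bottom: float = 0.04,
    threshold: float = 2000.0,
) -> pd.DataFrame:
    """Call overexpression toxicity from growth at 0 nM (x) and 100 nM (y).

    Strains in the top ``trim_top`` or bottom ``trim_bottom`` of either
    variable are removed before fitting ``y = m*x + b`` (trims applied to x
    and y separately, union removed).  All strains are then mapped onto the
    0 nM scale, ``y_corrected = (y - b)/m``, and the perpendicular distance
    from the diagonal ``|x - y_corrected| / sqrt(2)`` is computed.  A strain
    is toxic when that distance exceeds ``threshold`` *and* it lies below
    the diagonal (reduced growth); strains above the diagonal are never
    flagged.  The threshold is in the same absolute units as the growth
    totals (normalized pixel counts in the imaging pipeline).
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(df) < 50:
        raise ValueError(f"need >= 50 strains for a stable fit; got {len(df)}")

    keep = pd.Series(True, index=df.index)
    for col in ("x", "y"):
        lo = df[col].quantile(trim_bottom)
        hi = df[col].quantile(1 - trim_top)
        keep &= (df[col] >= lo) & (df[col] <= hi)
    fit_df = df[keep]
    model = sm.OLS(fit_df["y"], sm.add_constant(fit_df["x"])).fit()
    m = float(model.params["x"])
    b = float(model.params["const"])
    if m <= 0:
        raise RuntimeError(
            f"degenerate growth fit (slope {m:.3g} <= 0); cannot correct 100 nM values"
        )

    y_corr = (df["y"] - b) / m
    a, b_line, c = 1.0, -1.0, 0.0  # the diagonal y = x
    distance = np.abs(a * df["x"] + b_line * y_corr + c) / np.sqrt(a**2 + b_line**2)
    toxic = (distance > threshold) & (y_corr < df["x"])
    return pd.DataFrame(
        {
            "x_measured": df["x"],
            "y_measured": df["y"],
            "slope": m,
            "intercept": b,
            "y_corrected": y_corr,
            "distance": distance,
            "used_in_fit": keep,
            "toxic_flag": toxic,
        }
    )


def classify_reversibility(
    growth_without: float | np.ndarray | pd.Series,
    growth_with: float | np.ndarray | pd.Series,
    reversible_max: float = 0.55,
    partial_max: float = 0.75,
) -> pd.DataFrame:
    """Classify phenotype reversibility from the growth ratio without/with inducer.

    ratio <= 0.55 -> reversible; 0.55 < ratio <= 0.75 -> partially
    reversible; ratio > 0.75 -> not reversible.  Boundaries are inclusive on
    the left class, matching the printed cutoffs.  Undefined ratios
    (growth_with = 0) are flagged ``undefined``.
    """
    gw = pd.Series(np.atleast_1d(np.asarray(growth_with, dtype=float)))
    gwo = pd.Series(np.atleast_1d(np.asarray(growth_without, dtype=float)))
    if (gwo < 0).any() or (gw < 0).any():
        raise ValueError("growth values must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = gwo / gw
    cls = pd.Series("not_reversible", index=ratio.index, dtype=object)
    cls[ratio <= partial_max] = "partially_reversible"
    cls[ratio <= reversible_max] = "reversible"
    cls[~np.isfinite(ratio)] = "undefined"
    return pd.DataFrame({"ratio": ratio, "class": cls})


def classify_dependence(
    augc_by_dose: pd.Series,
    high_cutoff: float = 0.75,
    low_cutoff: float = 0.25,
    floor: float = 0.1,
) -> str:
    """Classify inducer dependence from an AUGC dose profile.

    ``no_growth`` if the profile never exceeds ``floor``; otherwise classify
    by the fraction of maximal growth retained at dose 0: >= ``high_cutoff``
    is constitutive, <= ``low_cutoff`` is dependent, in between is
    partially dependent.  Cutoffs are reported by the caller alongside the
    classes.
    """
    s = augc_by_dose.sort_index()
    if len(s) < 2:
        raise ValueError("dependence classification requires more than one dose")
    if 0.0 not in s.index:
        raise ValueError("dose 0 must be present")
    peak = float(s.max())
    if peak < floor:
        return "no_growth"
    frac0 = float(s.loc[0.0]) / peak
    if frac0 >= high_cutoff:
        return "constitutive"
    if frac0 <= low_cutoff:
        return "dependent"
    return "partially_dependent"


def sdl_call(
    sizes: pd.DataFrame,
    cutoff: float = -0.08,
    score: str = "log2",
) -> pd.DataFrame:
    """Call synthetic dosage lethality from replicated colony-size ratios.

    ``sizes`` columns: array_gene, replicate, size_1000, size_0 (normalized
    colony sizes at 1000 and 0 nM inducer, perimeter pre-excluded).  The
    per-replicate score is ``log2(size_1000/size_0)`` (or ``ratio - 1`` with
    ``score='ratio_minus_1'``); an interaction is called only when the score
    is below ``cutoff`` in *every* replicate.  Genes with an undefined
    replicate (size_0 = 0) are excluded and flagged.
    """
    if score not in ("log2", "ratio_minus_1"):
        raise ValueError(f"unknown score type {score!r}")
    df = sizes.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["size_1000"] / df["size_0"]
        df["score"] = np.log2(ratio) if score == "log2" else ratio - 1.0
    df["defined"] = np.isfinite(df["score"])
    per_gene = df.groupby("array_gene").agg(
        n_replicates=("replicate", "nunique"),
        n_below=("score", lambda s: int((s < cutoff).sum())),
        min_score=("score", "min"),
        max_score=("score", "max"),
        all_defined=("defined", "all"),
    )
    per_gene["sdl_flag"] = (
        per_gene["all_defined"]
        & (per_gene["n_below"] == df.groupby("array_gene").size())
    )
    per_gene["excluded_flag"] = ~per_gene["all_defined"]
    per_gene.loc[per_gene["excluded_flag"], "sdl_flag"] = False
    return per_gene.reset_index()


def score_config_header(config: ScoreConfig) -> dict:
    """Threshold echo for output-file provenance headers."""
    return config.model_dump()
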