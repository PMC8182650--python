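"""Strain panels: ground-truth metadata for simulation and joins.

A panel row describes one barcoded strain whose target gene is under
beta-estradiol control: its 12-nt barcode, dose-response archetype,
auxotrophy flag, injected toxicity effect, and native expression level.
Exactly one row is the wild-type spike-in used for BAR-seq normalization
and as the plate reference strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .config import ARCHETYPES, BARCODE_LENGTH, SimulationConfig

__all__ = ["StrainPanel", "make_strain_panel", "min_pairwise_hamming"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: strain_id of the wild-type spike-in appended to every panel.
WT_STRAIN_ID = "WT-SPIKEIN"

PANEL_COLUMNS = [
    "strain_id",
    "gene_name",
    "barcode",
    "essential",
    "native_expression",
    "archetype",
    "aux_flag",
    "toxicity_effect",
    "baseline_fitness",
    "is_spike_in_wt",
]


@dataclass
class StrainPanel:
    """Table of strains with simulation ground truth.

    ``table`` columns follow :data:`PANEL_COLUMNS`; invariants are checked
    by :meth:`validate`.
    """

    table: pd.DataFrame
    min_barcode_distance: int = 5

    def __post_init__(self) -> None:
        self.validate()

    @property
    def wt_strain(self) -> str:
        return str(self.table.loc[self.table["is_spike_in_wt"], "strain_id"].iloc[0])

    @property
    def barcodes(self) -> pd.Series:
        return self.table.set_index("strain_id")["barcode"]

    def validate(self) -> None:
        t = self.table
        missing = set(PANEL_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if t["barcode"].duplicated().any():
            raise ValueError("panel barcodes must be unique")
        if not t["barcode"].str.fullmatch(f"[ACGT]{{{BARCODE_LENGTH}}}").all():
            raise ValueError(f"barcodes must be {BARCODE_LENGTH}-nt ACGT strings")
        if int(t["is_spike_in_wt"].sum()) != 1:
            raise ValueError("panel must contain exactly one spike-in wild-type strain")
        if (t["native_expression"] < 0).any():
            raise ValueError("native_expression must be nonnegative")
        if (t["baseline_fitness"] <= 0).any():
            raise ValueError("baseline_fitness must be positive")
        if not t["archetype"].isin(ARCHETYPES).all():
            raise ValueError("unknown archetype in panel")
        d = min_pairwise_hamming(t["barcode"].tolist())
        if d < self.min_barcode_distance:
            raise ValueError(
                f"min pairwise barcode Hamming distance {d} < {self.min_barcode_distance}"
            )


def _encode(barcodes: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(barcodes).encode(), dtype=np.uint8)
    return arr.reshape(len(barcodes), -1)


def min_pairwise_hamming(barcodes: list[str]) -> int:
    """Minimum Hamming distance over all barcode pairs (vectorized)."""
    if len(barcodes) < 2:
        return BARCODE_LENGTH
    enc = _encode(barcodes)
    best = enc.shape[1]
    # row-block comparison keeps memory bounded for large panels
    for i in range(len(enc) - 1):
        d = (enc[i + 1 :] != enc[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
            if best == 0:
                break
    return best


def _sample_barcodes(n: int, min_distance: int, rng: np.random.Generator) -> list[str]:
    """Greedy rejection sampling of barcodes with pairwise distance >= min_distance."""
    accepted = np.empty((0, BARCODE_LENGTH), dtype=np.uint8)
    max_draws = max(200 * n, 10_000)
    draws = 0
    out: list[str] = []
    while len(out) < n:
        if draws >= max_draws:
            raise ValueError(
                f"could not sample {n} barcodes at min Hamming distance "
                f"{min_distance} after {max_draws} draws"
            )
        batch = _BASES[rng.integers(0, 4, size=(256, BARCODE_LENGTH))]
        draws += len(batch)
        for cand in batch:
            if len(out) >= n:
                break
            if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_distance:
                continue
            accepted = np.vstack([accepted, cand])
            out.append(cand.tobytes().decode())
    return out


def make_strain_panel(config: SimulationConfig) -> StrainPanel:
    """Draw a deterministic strain panel from the generator config.

    Archetypes are assigned by ``archetype_probs``; toxicity effects for the
    toxic archetypes are uniform on ``toxicity_effect_range``; auxotrophy is
    planted in a fraction of non-essential constitutive strains (auxotrophs
    grow on minimal medium only when the controlled gene is induced).  The
    wild-type spike-in is appended as an extra constitutive strain.
    """
    if config.n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    rng = substream(config.seed, "panel")
    n = config.n_strains
    barcodes = _sample_barcodes(n + 1, config.min_barcode_distance, rng)

    names = list(config.archetype_probs)
    probs = np.array([config.archetype_probs[a] for a in names])
    archetype = rng.choice(names, size=n, p=probs / probs.sum())

    lo, hi = config.toxicity_effect_range
    toxicity = np.where(
        np.char.endswith(archetype.astype(str), "_toxic"),
        rng.uniform(lo, hi, size=n),
        0.0,
    )
    # essentiality mirrors the archetype semantics: strains that need the
    # inducer (or never grow) carry essential genes
    essential = np.isin(archetype, ["dependent", "dependent_toxic", "nonfunctional"])
    aux_candidates = (~essential) & (archetype == "constitutive")
    aux_flag = aux_candidates & (rng.random(n) < config.aux_fraction / max(
        float(aux_candidates.mean()), 1e-9
    ))
    expr = rng.lognormal(
        mean=np.log(config.expression_median_tpm),
        sigma=config.expression_log_sigma,
        size=n,
    )
    # strain-to-strain baseline fitness: promoter-replacement alleles are not
    # perfectly isogenic in growth even within a behavior class
    fitness = rng.lognormal(mean=0.0, sigma=config.strain_fitness_sigma, size=n)

    table = pd.DataFrame(
        {
            "strain_id": [f"Y{i:05d}" for i in range(n)],
            "gene_name": [f"GENE{i:04d}" for i in range(n)],
            "barcode": barcodes[:n],
            "essential": essential,
            "native_expression": expr,
            "archetype": archetype,
            "aux_flag": aux_flag,
            "toxicity_effect": toxicity,
            "baseline_fitness": fitness,
            "is_spike_in_wt": False,
        }
    )
    wt = pd.DataFrame(
        {
            "strain_id": [WT_STRAIN_ID],
            "gene_name": ["WT"],
            "barcode": [barcodes[n]],
            "essential": [False],
            "native_expression": [float(config.expression_median_tpm)],
            "archetype": ["constitutive"],
            "aux_flag": [False],
            "toxicity_effect": [0.0],
            "baseline_fitness": [1.0],
            "is_spike_in_wt": [True],
        }
    )
    full = pd.concat([table, wt], ignore_index=True)
    return StrainPanel(full, min_barcode_distance=config.min_barcode_distance)
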