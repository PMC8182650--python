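"""Synthetic data generators: growth tables, plate images, BAR-seq runs.

The generative model is logistic colony growth whose carrying capacity is
modulated by a Hill function of the beta-estradiol dose, one response shape
per archetype:

* ``constitutive``        — full capacity at every dose;
* ``constitutive_toxic``  — full capacity at low dose, Hill-shaped decline
                            at high dose (fractional loss = toxicity_effect);
* ``nonfunctional``       — residual capacity everywhere (dead promoter);
* ``dependent``           — leaky residual at 0 nM rising to full capacity
                            with a Hill induction response;
* ``dependent_toxic``     — induction response multiplied by the toxicity
                            decline (rise then fall).

Auxotroph-flagged strains follow the induction response on minimal (YNB)
medium but are constitutive on complete (SC) medium.  Colony-size noise is
multiplicative log-normal; the log-sigma is chosen so the *relative* sd
equals ``noise_sd`` exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .config import LAYOUTS, SimulationConfig, UP_FLANK, DOWN_FLANK
from .panel import StrainPanel, make_strain_panel

__all__ = [
    "simulate_growth",
    "render_plate",
    "render_plate_series",
    "make_barseq_design",
    "simulate_pool_abundances",
    "simulate_barseq_run",
    "toxicity_screen",
    "PlateImage",
]


# ---------------------------------------------------------------------------
# growth tables


def _hill(dose: np.ndarray, ec50: float, n: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = dose**n / (dose**n + ec50**n)
    return np.where(dose > 0, h, 0.0)


def capacity_fraction(
    archetype: np.ndarray,
    aux_flag: np.ndarray,
    toxicity_effect: np.ndarray,
    dose: np.ndarray,
    medium: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Fraction of full carrying capacity for each (strain, dose) pair.

    ``archetype``/``aux_flag``/``toxicity_effect`` are per-strain arrays;
    ``dose`` is the dose grid.  Returns shape (n_strains, n_doses).
    """
    dose = np.asarray(dose, dtype=float)
    ind = _hill(dose, config.ec50_nM, config.hill_n)[None, :]
    tox = _hill(dose, config.tox_ec50_nM, config.tox_hill_n)[None, :]
    leak = config.leak_fraction

    arch = np.asarray(archetype, dtype=object).copy()
    if medium == "YNB":
        # auxotrophs need the induced gene product on minimal medium
        arch[np.asarray(aux_flag, dtype=bool)] = "dependent"

    n_strains, n_doses = len(arch), len(dose)
    f = np.empty((n_strains, n_doses))
    eff = np.asarray(toxicity_effect, dtype=float)[:, None]
    induction = leak + (1.0 - leak) * ind
    for name, expr in {
        "constitutive": np.broadcast_to(1.0 - 0.0 * tox, (n_strains, n_doses)),
        "constitutive_toxic": 1.0 - eff * tox,
        "nonfunctional": np.full((n_strains, n_doses), config.nonfunctional_capacity),
        "dependent": np.broadcast_to(induction, (n_strains, n_doses)),
        "dependent_toxic": induction * (1.0 - eff * tox),
    }.items():
        mask = arch == name
        if mask.any():
            f[mask] = np.broadcast_to(expr, (n_strains, n_doses))[mask]
    return np.clip(f, config.nonfunctional_capacity / 2, 1.0)


def _logistic(t: np.ndarray, a0: float, k: np.ndarray, r: float) -> np.ndarray:
    """Logistic colony area; broadcasts K over a trailing time axis."""
    k = np.maximum(np.asarray(k, dtype=float), 1e-9)[..., None]
    t = np.asarray(t, dtype=float)
    return k / (1.0 + (k - a0) / a0 * np.exp(-r * t))


def simulate_growth(panel: StrainPanel, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the colony-growth table for every strain x medium x dose x time.

    Returns a long table with columns strain_id, medium, dose_nM, time_h,
    replicate, true_area, area; ``true_area`` is the noise-free ground truth
    retained for tests, ``area`` carries multiplicative log-normal noise with
    relative sd ``config.noise_sd``.
    """
    if not config.doses:
        raise ValueError("dose list is empty")
    if not config.timepoints:
        raise ValueError("timepoint list is empty")
    panel.validate()
    rng = substream(config.seed, "growth")
    t = np.asarray(config.timepoints, dtype=float)
    doses = np.asarray(config.doses, dtype=float)
    tab = panel.table
    frames = []
    sigma = float(np.sqrt(np.log1p(config.noise_sd**2)))
    for medium in config.media:
        f = capacity_fraction(
            tab["archetype"].to_numpy(),
            tab["aux_flag"].to_numpy(),
            tab["toxicity_effect"].to_numpy(),
            doses,
            medium,
            config,
        )
        k = f * config.carrying_capacity * tab["baseline_fitness"].to_numpy()[:, None]
        true = _logistic(t, config.initial_area, k, config.growth_rate)
        # true: (strains, doses, times); replicate axis gets independent noise
        shape = (len(tab), len(doses), config.replicates, len(t))
        noise = np.exp(rng.normal(0.0, sigma, size=shape)) if sigma > 0 else 1.0
        noisy = np.broadcast_to(true[:, :, None, :] * noise, shape)
        idx = pd.MultiIndex.from_product(
            [tab["strain_id"], doses, range(config.replicates), t],
            names=["strain_id", "dose_nM", "replicate", "time_h"],
        )
        df = pd.DataFrame(
            {
                "true_area": np.broadcast_to(true[:, :, None, :], shape).ravel(),
                "area": np.asarray(noisy).ravel(),
            },
            index=idx,
        ).reset_index()
        df.insert(1, "medium", medium)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# plate rendering


@dataclass
class PlateImage:
    """A rendered plate: 16-bit image plus per-position ground truth."""

    plate_id: str
    image: np.ndarray
    truth: pd.DataFrame  # row, col, strain_id, requested_area, true_pixel_area
    meta: dict = field(default_factory=dict)


def render_plate(
    area_grid: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one plate image from a (n_rows, n_cols) grid of colony areas.

    Colonies are near-circular intensity disks on a background plane with a
    configurable left-to-right gradient and Gaussian pixel noise.  Returns
    (image uint16, realized pixel-area grid, metadata).
    """
    area_grid = np.asarray(area_grid, dtype=float)
    n_rows, n_cols = area_grid.shape
    pitch = config.grid_pitch
    margin = pitch
    h = 2 * margin + (n_rows - 1) * pitch
    w = 2 * margin + (n_cols - 1) * pitch
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    img = config.background_level * (
        1.0 + config.background_gradient * (xx / max(w - 1, 1) - 0.5)
    ) * np.ones((h, 1))

    realized = np.zeros_like(area_grid)
    half = pitch // 2
    for i in range(n_rows):
        cy = margin + i * pitch
        for j in range(n_cols):
            a = area_grid[i, j]
            if a <= 0:
                continue
            cx = margin + j * pitch
            r = np.sqrt(a / np.pi)
            y0, y1 = cy - half, cy + half + 1
            x0, x1 = cx - half, cx + half + 1
            dy = np.arange(y0, y1)[:, None] - cy
            dx = np.arange(x0, x1)[None, :] - cx
            disk = dy * dy + dx * dx <= r * r
            img[y0:y1, x0:x1][disk] += config.foreground_level
            realized[i, j] = int(disk.sum())

    if config.pixel_noise_sd > 0:
        if rng is None:
            rng = substream(config.seed, "render")
        img = img + rng.normal(0.0, config.pixel_noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    meta = {
        "pitch": pitch,
        "margin": margin,
        "n_rows": n_rows,
        "n_cols": n_cols,
        "height": h,
        "width": w,
    }
    return img, realized, meta


def assign_layout(
    strain_ids: list[str],
    layout: int,
    replicates: int,
    border_strain: str,
) -> pd.DataFrame:
    """Assign strains to grid positions: border filled with the reference
    strain, interior positions row-major with ``replicates`` copies each;
    leftover interior positions also carry the reference strain (plates are
    never pinned sparse)."""
    n_rows, n_cols = LAYOUTS[layout]
    interior = [
        (r, c)
        for r in range(1, n_rows - 1)
        for c in range(1, n_cols - 1)
    ]
    need = len(strain_ids) * replicates
    if need > len(interior):
        raise ValueError(
            f"{len(strain_ids)} strains x {replicates} replicates do not fit "
            f"the {layout} layout interior ({len(interior)} positions)"
        )
    rows = []
    for r in range(n_rows):
        for c in range(n_cols):
            if r in (0, n_rows - 1) or c in (0, n_cols - 1):
                rows.append((r, c, border_strain, 0))
    for k, (r, c) in enumerate(interior):
        if k < need:
            rows.append((r, c, strain_ids[k // replicates], k % replicates))
        else:
            rows.append((r, c, border_strain, k % replicates))
    return pd.DataFrame(rows, columns=["row", "col", "strain_id", "replicate"])


def render_plate_series(
    growth: pd.DataFrame,
    layout: int,
    config: SimulationConfig,
    border_strain: str,
) -> list[PlateImage]:
    """Render one plate per (medium, dose, time) from a simulated growth table.

    The plate border carries the reference strain; interior positions hold
    replicate colonies of each strain.  Ground truth records both the
    requested area and the realized (discretized) pixel area.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout}")
    strains = [s for s in growth["strain_id"].unique() if s != border_strain]
    pos = assign_layout(strains, layout, config.replicates, border_strain)
    n_rows, n_cols = LAYOUTS[layout]
    rng = substream(config.seed, "render")
    plates = []
    lookup = growth.set_index(["medium", "dose_nM", "time_h", "strain_id", "replicate"])[
        "area"
    ].sort_index()
    for (medium, dose, time), _ in growth.groupby(["medium", "dose_nM", "time_h"]):
        grid = np.zeros((n_rows, n_cols))
        sub = lookup.loc[(medium, dose, time)]
        for row in pos.itertuples(index=False):
            rep = max(row.replicate, 0)
            try:
                grid[row.row, row.col] = float(sub.loc[(row.strain_id, rep)])
            except KeyError:
                grid[row.row, row.col] = 0.0
        img, realized, meta = render_plate(grid, config, rng)
        truth = pos.copy()
        truth["requested_area"] = grid[truth["row"], truth["col"]]
        truth["true_pixel_area"] = realized[truth["row"], truth["col"]]
        plate_id = f"{medium}_d{dose:g}_t{time:g}"
        meta.update({"medium": medium, "dose_nM": dose, "time_h": time})
        plates.append(PlateImage(plate_id, img, truth, meta))
    return plates


# ---------------------------------------------------------------------------
# toxicity screen totals


def toxicity_screen(
    n_strains: int = 5000,
    toxic_fraction: float = 0.05,
    seed: int = 0,
    baseline_median: float = 10_000.0,
    baseline_log_sigma: float = 0.25,
    noise_sd: float = 0.05,
    effect_range: tuple[float, float] = (0.6, 0.9),
) -> pd.DataFrame:
    """Simulate total growth at 0 and 100 nM for an overexpression screen.

    Totals are on the normalized-pixel scale of the imaging pipeline
    (~10^4 units), so the absolute diagonal-distance cutoff used by the
    toxicity caller applies directly.  Toxic strains lose at least half
    their growth at 100 nM.
    """
    rng = substream(seed, "toxscreen")
    base = rng.lognormal(np.log(baseline_median), baseline_log_sigma, size=n_strains)
    toxic = rng.random(n_strains) < toxic_fraction
    effect = np.where(toxic, rng.uniform(*effect_range, size=n_strains), 0.0)
    sigma = float(np.sqrt(np.log1p(noise_sd**2)))
    x = base * np.exp(rng.normal(0, sigma, n_strains))
    y = base * (1 - effect) * np.exp(rng.normal(0, sigma, n_strains))
    return pd.DataFrame(
        {
            "strain_id": [f"Y{i:05d}" for i in range(n_strains)],
            "growth_0nM": x,
            "growth_100nM": y,
            "is_toxic": toxic,
            "toxicity_effect": effect,
        }
    )


# ---------------------------------------------------------------------------
# BAR-seq


def make_barseq_design(
    media: tuple[str, ...] = ("SC", "YNB"),
    doses: tuple[float, ...] = (0.0, 100.0),
    n_t0: int = 3,
    times: dict[str, tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Sample sheet for a pooled competitive-growth run.

    Default sampling: three time-0 samples per medium, then each dose arm
    sampled at 9/18/36 h in SC and 12/24/48 h in YNB.
    """
    if times is None:
        times = {"SC": (9.0, 18.0, 36.0), "YNB": (12.0, 24.0, 48.0)}
    rows = []
    for medium in media:
        for rep in range(n_t0):
            rows.append((f"{medium}_t0_r{rep}", medium, 0.0, 0.0, rep))
        for dose in doses:
            for t in times[medium]:
                rows.append((f"{medium}_d{dose:g}_t{t:g}", medium, dose, t, 0))
    return pd.DataFrame(
        rows, columns=["sample_id", "medium", "dose_nM", "time_h", "replicate"]
    )


def simulate_pool_abundances(
    panel: StrainPanel, design: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative strain abundances per sample, with planted log2FC truth.

    Planted patterns follow the panel ground truth: auxotrophs deplete in
    minimal medium without inducer; toxic strains deplete in induced arms.
    Depletion grows linearly in time to ``planted_log2fc`` log2 units at the
    final timepoint of each arm.  The wild-type spike-in starts at
    ``spike_in_fraction`` of the pool and is neutral.

    Returns (abundances, planted_log2fc), both strains x samples.
    """
    tab = panel.table
    rng = substream(config.seed, "pool")
    n = len(tab)
    a0 = np.exp(rng.normal(0.0, config.abundance_log2_sigma * np.log(2), size=n))
    wt_mask = tab["is_spike_in_wt"].to_numpy()
    others = a0[~wt_mask].sum()
    a0[wt_mask] = config.spike_in_fraction / (1 - config.spike_in_fraction) * others

    t_final = design.groupby("medium")["time_h"].transform("max").to_numpy()
    l2 = np.zeros((n, len(design)))
    aux = tab["aux_flag"].to_numpy()
    toxic = (tab["toxicity_effect"].to_numpy() > 0) & ~wt_mask
    for s, row in enumerate(design.itertuples(index=False)):
        frac = row.time_h / t_final[s] if t_final[s] > 0 else 0.0
        if row.medium == "YNB" and row.dose_nM == 0:
            l2[aux, s] = -config.planted_log2fc * frac
        if row.dose_nM > 0:
            l2[toxic, s] = -config.planted_log2fc * frac
    ab = a0[:, None] * 2.0**l2
    idx = tab["strain_id"]
    cols = design["sample_id"]
    return (
        pd.DataFrame(ab, index=idx, columns=cols),
        pd.DataFrame(l2, index=idx, columns=cols),
    )


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _reads_for_sample(
    barcodes: list[str],
    counts: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reads as a (n_reads, read_length) uint8 array with substitution errors."""
    L = config.read_length
    core_len = len(UP_FLANK) + len(barcodes[0]) + len(DOWN_FLANK)
    if L < core_len:
        raise ValueError(f"read_length {L} shorter than flank+barcode core {core_len}")
    n_reads = int(counts.sum())
    reads = np.empty((n_reads, L), dtype=np.uint8)
    up = np.frombuffer(UP_FLANK.encode(), dtype=np.uint8)
    down = np.frombuffer(DOWN_FLANK.encode(), dtype=np.uint8)
    pos = 0
    for bc, c in zip(barcodes, counts):
        if c == 0:
            continue
        core = np.concatenate([up, np.frombuffer(bc.encode(), dtype=np.uint8), down])
        reads[pos : pos + c, :core_len] = core
        pos += int(c)
    # random filler after the core, then shuffle read order
    filler = _BASES_ARR[rng.integers(0, 4, size=(n_reads, L - core_len))]
    reads[:, core_len:] = filler
    rng.shuffle(reads, axis=0)

    if config.per_base_error > 0:
        # chunked substitution errors: replace with one of the 3 other bases
        chunk = 200_000
        for start in range(0, n_reads, chunk):
            block = reads[start : start + chunk]
            mask = rng.random(block.shape) < config.per_base_error
            if not mask.any():
                continue
            idx = _BASE_INDEX[block[mask]]
            new_idx = (idx + rng.integers(1, 4, size=idx.shape)) % 4
            block[mask] = _BASES_ARR[new_idx]
    return reads


_BASES_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def simulate_barseq_run(
    panel: StrainPanel,
    abundances: pd.DataFrame,
    config: SimulationConfig,
    outdir: str | Path,
) -> pd.DataFrame:
    """Write one FASTQ per sample and return the true pre-error count table.

    Each read is ``[up flank][12-nt barcode][down flank][random filler]``
    with independent per-base substitution errors; counts per sample are
    multinomial on the normalized abundances at ``read_depth`` reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bc = panel.barcodes
    ab = abundances.reindex(bc.index)
    if ab.isna().any().any():
        raise ValueError("abundances missing strains present in the panel")
    if (ab < 0).any().any():
        raise ValueError("abundances must be nonnegative")
    rng = substream(config.seed, "barseq")
    true_counts = {}
    qual = "I" * config.read_length
    barcodes = bc.tolist()
    for sample in ab.columns:
        a = ab[sample].to_numpy(dtype=float)
        total = a.sum()
        if total <= 0:
            raise ValueError(f"sample {sample}: all abundances are zero")
        counts = rng.multinomial(config.read_depth, a / total)
        true_counts[sample] = counts
        reads = _reads_for_sample(barcodes, counts, config, rng)
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            buf = []
            for i in range(reads.shape[0]):
                seq = reads[i].tobytes().decode()
                buf.append(f"@{sample}:{i}\n{seq}\n+\n{qual}\n")
                if len(buf) >= 50_000:
                    fh.write("".join(buf))
                    buf = []
            fh.write("".join(buf))
    return pd.DataFrame(true_counts, index=bc.index)
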