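"""End-to-end pipeline binding simulation, quantification, and scoring.

``run_pipeline`` executes the requested stages in their canonical order
(simulate, quantify, growth, cluster, score, barseq), writing each stage's
outputs as TSV/FASTQ/images under one output directory and recording a JSON
manifest with the config echo, seed, per-stage timing, and output
checksums.  With a fixed config and seed every deterministic stage
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as zio
from .barseq import build_index, cluster_fitness, count_reads, fitness_log2fc
from .clustering import cluster_profiles
from .config import PipelineConfig
from .growth import build_curves, compute_augc_matrix
from .panel import make_strain_panel
from .plates import normalize_sizes, quantify_plate
from .scores import (
    aux_scores,
    classify_dependence,
    classify_reversibility,
    sdl_call,
    toxicity_call,
)
from .simulate import (
    make_barseq_design,
    render_plate_series,
    simulate_barseq_run,
    simulate_growth,
    simulate_pool_abundances,
)

STAGES = ("simulate", "quantify", "growth", "cluster", "score", "barseq")

__all__ = ["run_pipeline", "STAGES", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries an exit code for the CLI."""

    def __init__(self, message: str, exit_code: int = 4):
        super().__init__(message)
        self.exit_code = exit_code


def _growth_totals(growth: pd.DataFrame, medium: str, dose: float) -> pd.Series:
    """Total growth per strain: colony areas summed over times and replicates."""
    sub = growth[(growth["medium"] == medium) & (growth["dose_nM"] == dose)]
    return sub.groupby("strain_id")["area"].sum()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages and return the manifest dict."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stages: {bad}", exit_code=2)
    stages = tuple(s for s in STAGES if s in stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "zevphen",
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "stages": {},
        "outputs": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    state: dict = {}
    for stage in stages:
        start = time.time()
        try:
            _STAGE_FUNCS[stage](config, outdir, state)
        except PipelineError:
            raise
        except FileNotFoundError as exc:
            raise PipelineError(f"stage {stage!r}: missing input: {exc}", exit_code=3) from exc
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}", exit_code=4) from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - start, 3)}

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = zio.sha256_file(path)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    zio.write_manifest(outdir / "manifest.json", manifest)
    return manifest


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict) -> None:
    panel = make_strain_panel(config.sim)
    growth = simulate_growth(panel, config.sim)
    zio.write_tsv(panel.table, outdir / "panel.tsv", {"seed": config.seed})
    zio.write_tsv(growth, outdir / "growth_true.tsv")
    # plates rendered for SC only; other media are analyzed from the table
    sc = growth[growth["medium"] == "SC"]
    plates = render_plate_series(sc, config.layout, config.sim, panel.wt_strain)
    (outdir / "plates").mkdir(exist_ok=True)
    truth_frames = []
    for plate in plates:
        zio.write_image(plate.image, outdir / "plates" / f"{plate.plate_id}.tif")
        t = plate.truth.copy()
        for key in ("medium", "dose_nM", "time_h"):
            t[key] = plate.meta[key]
        t["plate_id"] = plate.plate_id
        truth_frames.append(t)
    zio.write_tsv(pd.concat(truth_frames, ignore_index=True), outdir / "plate_truth.tsv")

    design = make_barseq_design(
        media=("SC",), doses=(0.0, 100.0), n_t0=3, times={"SC": (9.0, 18.0, 36.0)}
    )
    abundances, planted = simulate_pool_abundances(panel, design, config.sim)
    true_counts = simulate_barseq_run(panel, abundances, config.sim, outdir / "fastq")
    zio.write_tsv(design, outdir / "barseq_samples.tsv")
    zio.write_tsv(planted.reset_index(), outdir / "barseq_planted_log2fc.tsv")
    zio.write_tsv(true_counts.reset_index(), outdir / "barseq_true_counts.tsv")
    state.update(panel=panel, growth=growth, plates=plates, design=design)


def _stage_quantify(config: PipelineConfig, outdir: Path, state: dict) -> None:
    truth, _ = zio.read_tsv(outdir / "plate_truth.tsv")
    frames = []
    for plate_id, tmap in truth.groupby("plate_id"):
        image = zio.read_image(outdir / "plates" / f"{plate_id}.tif")
        meta = {
            "plate_id": plate_id,
            "medium": tmap["medium"].iloc[0],
            "dose_nM": float(tmap["dose_nM"].iloc[0]),
            "time_h": float(tmap["time_h"].iloc[0]),
        }
        frames.append(quantify_plate(image, config.layout, meta, tmap, config.quant))
    sizes = pd.concat(frames, ignore_index=True)
    normalized = normalize_sizes(sizes, config.layout, config.quant)
    zio.write_tsv(normalized, outdir / "sizes.tsv", {"layout": config.layout})
    state["sizes"] = normalized


def _stage_growth(config: PipelineConfig, outdir: Path, state: dict) -> None:
    sizes, _ = zio.read_tsv(outdir / "sizes.tsv")
    panel, _ = zio.read_tsv(outdir / "panel.tsv")
    wt = config.growth.reference_strain or panel.loc[
        panel["is_spike_in_wt"], "strain_id"
    ].iloc[0]
    usable = sizes[~sizes["excluded_flag"] | (sizes["strain_id"] == wt)]
    curves = build_curves(usable, span=config.growth.loess_span)
    mat = compute_augc_matrix(curves, reference_strain=wt, medium="SC")
    out = mat.values.reset_index().rename(columns={"index": "strain_id"})
    zio.write_tsv(out, outdir / "augc.tsv", {"reference_strain": wt})
    state["augc"] = mat


def _stage_cluster(config: PipelineConfig, outdir: Path, state: dict) -> None:
    augc, _ = zio.read_tsv(outdir / "augc.tsv")
    values = augc.set_index("strain_id")
    values.columns = values.columns.astype(float)
    k = min(config.cluster.k, max(len(values) - 1, 2))
    prof = cluster_profiles(values, k=k, metric=config.cluster.metric,
                            linkage_method=config.cluster.linkage)
    zio.write_tsv(prof.assignments, outdir / "clusters.tsv", {"k": k})


def _stage_score(config: PipelineConfig, outdir: Path, state: dict) -> None:
    growth, _ = zio.read_tsv(outdir / "growth_true.tsv")
    sc = config.score
    echo = sc.model_dump()

    doses = sorted(growth["dose_nM"].unique())
    media = growth["medium"].unique()
    if "YNB" in media and 1.0 in doses:
        g = pd.DataFrame(
            {
                "G_M0": _growth_totals(growth, "YNB", 0.0),
                "G_M1": _growth_totals(growth, "YNB", 1.0),
                "G_R0": _growth_totals(growth, "SC", 0.0),
                "G_R1": _growth_totals(growth, "SC", 1.0),
            }
        ).reset_index(names="strain_id")
        zio.write_tsv(aux_scores(g, sc.aux_pseudogrowth), outdir / "aux_scores.tsv", echo)

    if 100.0 in doses:
        x = _growth_totals(growth, "SC", 0.0)
        y = _growth_totals(growth, "SC", 100.0)
        # the caller assumes a 1:1 growth relation; strains that barely grow
        # without inducer (inducer-dependent alleles) violate it and are
        # screened separately by the dose-response clustering
        grows = x >= 0.2 * x.quantile(0.9)
        if int(grows.sum()) >= 50:
            tox = toxicity_call(
                x[grows], y[grows], sc.tox_trim_top, sc.tox_trim_bottom, sc.tox_threshold
            )
            zio.write_tsv(tox.reset_index(names="strain_id"), outdir / "toxicity.tsv", echo)
        rev = classify_reversibility(x, y, sc.rev_reversible_max, sc.rev_partial_max)
        rev.insert(0, "strain_id", x.index)
        zio.write_tsv(rev, outdir / "reversibility.tsv", echo)

    augc, _ = zio.read_tsv(outdir / "augc.tsv")
    values = augc.set_index("strain_id")
    values.columns = values.columns.astype(float)
    dep = pd.DataFrame(
        {
            "strain_id": values.index,
            "class": [
                classify_dependence(row, sc.dep_high_cutoff, sc.dep_low_cutoff, sc.dep_floor)
                for _, row in values.iterrows()
            ],
        }
    )
    zio.write_tsv(dep, outdir / "dependence.tsv", echo)

    if max(doses) >= 1000.0:
        sdl_rows = []
        for rep in sorted(growth["replicate"].unique())[:2]:
            sub = growth[growth["replicate"] == rep]
            final_t = sub["time_h"].max()
            final = sub[(sub["time_h"] == final_t) & (sub["medium"] == "SC")]
            s0 = final[final["dose_nM"] == 0.0].set_index("strain_id")["area"]
            s1000 = final[final["dose_nM"] == 1000.0].set_index("strain_id")["area"]
            sdl_rows.append(
                pd.DataFrame(
                    {
                        "array_gene": s0.index,
                        "replicate": rep,
                        "size_1000": s1000.reindex(s0.index).to_numpy(),
                        "size_0": s0.to_numpy(),
                    }
                )
            )
        sdl = sdl_call(pd.concat(sdl_rows, ignore_index=True), sc.sdl_cutoff, sc.sdl_score)
        zio.write_tsv(sdl, outdir / "sdl.tsv", echo)


def _stage_barseq(config: PipelineConfig, outdir: Path, state: dict) -> None:
    panel, _ = zio.read_tsv(outdir / "panel.tsv")
    design, _ = zio.read_tsv(outdir / "barseq_samples.tsv")
    wt = panel.loc[panel["is_spike_in_wt"], "strain_id"].iloc[0]
    index = build_index(panel[["strain_id", "barcode"]], config.barseq.max_mismatch)
    fastqs = {
        row.sample_id: outdir / "fastq" / f"{row.sample_id}.fastq"
        for row in design.itertuples(index=False)
    }
    for path in fastqs.values():
        if not Path(path).exists():
            raise FileNotFoundError(path)
    cm = count_reads(
        fastqs, index, design,
        config.barseq.flank_max_mismatch, config.barseq.flank_max_shift,
    )
    zio.write_tsv(cm.counts.reset_index(names="strain_id"), outdir / "barseq_counts.tsv")
    zio.write_tsv(cm.totals.reset_index(), outdir / "barseq_totals.tsv")
    fm = fitness_log2fc(cm, wt, config.barseq.floor_quantile)
    zio.write_tsv(
        fm.values.reset_index(names="strain_id"),
        outdir / "barseq_fitness.tsv",
        {"floor": fm.floor, "wt_strain": wt},
    )
    k = min(config.barseq.k, len(fm.values) - 1)
    clusters = cluster_fitness(fm, k, wt, config.barseq.depletion_threshold)
    zio.write_tsv(clusters, outdir / "barseq_clusters.tsv", {"k": k})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "growth": _stage_growth,
    "cluster": _stage_cluster,
    "score": _stage_score,
    "barseq": _stage_barseq,
}
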