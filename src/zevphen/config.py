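"""Configuration models for simulation and the end-to-end pipeline.

All models are strict (unknown keys rejected) and round-trip losslessly
through JSON/YAML, which the run manifest relies on.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: The 12-point beta-estradiol dose grid (nM) used for dose-response profiling.
DEFAULT_DOSES = [0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]

#: The five dose-response behavior archetypes.
ARCHETYPES = (
    "constitutive",
    "constitutive_toxic",
    "nonfunctional",
    "dependent_toxic",
    "dependent",
)

#: Default archetype mix: dominated by inducer-dependent strains, with smaller
#: constitutive, toxic, and promoter-dead fractions.
DEFAULT_ARCHETYPE_PROBS = {
    "dependent": 0.49,
    "dependent_toxic": 0.047,
    "constitutive": 0.33,
    "constitutive_toxic": 0.092,
    "nonfunctional": 0.042,
}

UP_FLANK = "GCACCAGGAACCATATA"
DOWN_FLANK = "GATCCGCTCGCACCG"
BARCODE_LENGTH = 12

#: Plate layouts: name -> (n_rows, n_cols).
LAYOUTS = {384: (16, 24), 1536: (32, 48)}


class SimulationConfig(BaseModel):
    """Ground-truth generator settings.

    The growth machinery (logistic curves, Hill dose response) is invented
    simulation plumbing: any model reproducing the five archetype shapes
    would do.  Parameters are in hours, nM, and pixel-area units.
    """

    model_config = ConfigDict(extra="forbid")

    n_strains: int = 500
    doses: list[float] = Field(default_factory=lambda: list(DEFAULT_DOSES))
    timepoints: list[float] = Field(default_factory=lambda: [float(t) for t in range(0, 25, 2)])
    media: list[str] = Field(default_factory=lambda: ["SC", "YNB"])
    replicates: int = 4
    noise_sd: float = 0.05
    seed: int = 0

    # strain panel
    archetype_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_PROBS)
    )
    aux_fraction: float = 0.05
    toxicity_effect_range: tuple[float, float] = (0.6, 0.9)
    expression_median_tpm: float = 30.0
    expression_log_sigma: float = 1.2
    min_barcode_distance: int = 5
    strain_fitness_sigma: float = 0.1  # ln-sd of per-strain baseline fitness

    # logistic / Hill growth machinery (invented, not measured quantities)
    carrying_capacity: float = 200.0   # saturating colony area, pixels
    initial_area: float = 5.0          # pinned inoculum area, pixels
    growth_rate: float = 0.45          # logistic rate, 1/h
    ec50_nM: float = 1.0               # induction half-maximal dose
    hill_n: float = 1.5
    tox_ec50_nM: float = 30.0          # toxicity half-maximal dose
    tox_hill_n: float = 2.0
    leak_fraction: float = 0.02        # capacity fraction at 0 nM for dependent strains
    nonfunctional_capacity: float = 0.02

    # plate rendering
    grid_pitch: int = 24               # pixels between adjacent colony centers
    background_level: float = 1000.0   # 16-bit grayscale baseline
    foreground_level: float = 4000.0   # additive colony intensity
    background_gradient: float = 0.2   # relative left-to-right background slope
    pixel_noise_sd: float = 30.0

    # BAR-seq
    read_depth: int = 1_000_000
    per_base_error: float = 0.005
    spike_in_fraction: float = 0.03
    read_length: int = 50
    abundance_log2_sigma: float = 1.443  # ln-sigma 1.0 expressed in log2 units
    planted_log2fc: float = 1.2          # terminal |log2FC| of planted depleted strains

    @field_validator("doses")
    @classmethod
    def _doses_sorted_nonneg(cls, v: list[float]) -> list[float]:
        if any(d < 0 for d in v):
            raise ValueError("doses must be nonnegative")
        if sorted(v) != v:
            raise ValueError("doses must be sorted ascending")
        return v

    @field_validator("timepoints")
    @classmethod
    def _times_sorted(cls, v: list[float]) -> list[float]:
        if sorted(v) != v or len(set(v)) != len(v):
            raise ValueError("timepoints must be strictly increasing")
        return v

    @field_validator("media")
    @classmethod
    def _media_known(cls, v: list[str]) -> list[str]:
        bad = set(v) - {"SC", "YNB"}
        if bad:
            raise ValueError(f"unknown media: {sorted(bad)}")
        if not v:
            raise ValueError("media must be non-empty")
        return v

    @model_validator(mode="after")
    def _check_probs(self) -> "SimulationConfig":
        if set(self.archetype_probs) - set(ARCHETYPES):
            raise ValueError("archetype_probs has unknown archetypes")
        # the default mix quotes rounded percentages, so allow slight drift;
        # proportions are renormalized when strains are drawn
        total = sum(self.archetype_probs.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"archetype_probs must sum to 1, got {total}")
        return self


class QuantConfig(BaseModel):
    """Colony quantification and normalization parameters."""

    model_config = ConfigDict(extra="forbid")

    layout: int = 384
    mad_k: float = 3.0              # threshold = local median + k * MAD
    window_pitches: float = 2.0     # adaptive-threshold window span, in grid pitches
    spatial_window: int = 7         # moving-median window, grid cells
    empty_fraction: float = 0.1     # normalized size below which a colony counts as empty
    competition_min_empty: int = 2  # empty 8-neighbors required to trigger the cap
    min_measurable: float = 0.5     # plates with fewer measurable colonies are low-quality

    @field_validator("layout")
    @classmethod
    def _known_layout(cls, v: int) -> int:
        if v not in LAYOUTS:
            raise ValueError(f"layout must be one of {sorted(LAYOUTS)}")
        return v


class GrowthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    loess_span: float = 0.3
    reference_strain: Optional[str] = None  # None -> the panel's spike-in wild type


class ClusterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: int = 5
    metric: str = "chebyshev"
    linkage: str = "average"
    low_threshold: float = 0.2    # "low" = below this fraction of reference growth
    fall_threshold: float = 0.3   # "fall" = more than this drop from the profile peak
    n_bins: int = 6


class ScoreConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    aux_pseudogrowth: float = 1e-3
    tox_trim_top: float = 0.02
    tox_trim_bottom: float = 0.04
    tox_threshold: float = 2000.0
    rev_reversible_max: float = 0.55
    rev_partial_max: float = 0.75
    dep_high_cutoff: float = 0.75
    dep_low_cutoff: float = 0.25
    dep_floor: float = 0.1
    sdl_cutoff: float = -0.08
    sdl_score: str = "log2"  # or "ratio_minus_1"


class BarseqConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_mismatch: int = 2
    flank_max_mismatch: int = 1
    flank_max_shift: int = 2
    floor_quantile: float = 0.05
    k: int = 3
    depletion_threshold: float = 0.5


class PipelineConfig(BaseModel):
    """Full pipeline configuration; one global seed feeds named substreams."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    layout: int = 384
    sim: SimulationConfig = Field(default_factory=SimulationConfig)
    quant: QuantConfig = Field(default_factory=QuantConfig)
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    score: ScoreConfig = Field(default_factory=ScoreConfig)
    barseq: BarseqConfig = Field(default_factory=BarseqConfig)

    @model_validator(mode="after")
    def _propagate_seed(self) -> "PipelineConfig":
        # the global seed wins; stage configs never carry their own
        self.sim.seed = self.seed
        self.quant.layout = self.layout
        return self
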