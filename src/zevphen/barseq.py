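"""BAR-seq: barcode counting, spike-in/t0-normalized fitness, clustering.

Reads carry a strain-specific 12-nt barcode between two universal flanks.
Counting locates the upstream flank (exact, or one mismatch, with a small
positional shift), extracts the barcode, verifies the downstream flank,
and assigns the barcode to the unique strain within the mismatch budget.
Assignment uses a precomputed Hamming-ball lookup over all barcode
variants within ``max_mismatch`` substitutions, which is exactly
equivalent to an exhaustive Hamming scan over the index: a variant inside
one strain's ball maps to that strain, a variant inside two or more balls
is ambiguous, anything else is unassigned.

Fitness is the log2 fold change of each strain's wild-type-spike-in-
relative abundance against the (geometric) mean of its time-0 samples,
after flooring counts at a low quantile of the pooled t0 distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import BARCODE_LENGTH, DOWN_FLANK, UP_FLANK
from .panel import min_pairwise_hamming

__all__ = [
    "BarcodeIndex",
    "CountMatrix",
    "FitnessMatrix",
    "build_index",
    "count_reads",
    "fitness_log2fc",
    "cluster_fitness",
    "hamming",
]

#: sentinel for barcode variants claimed by more than one strain
AMBIGUOUS = "__AMBIGUOUS__"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _ball(barcode: str, radius: int) -> set[str]:
    """All sequences within ``radius`` substitutions of ``barcode``."""
    out = {barcode}
    for r in range(1, radius + 1):
        for positions in itertools.combinations(range(len(barcode)), r):
            for subs in itertools.product("ACGT", repeat=r):
                if any(barcode[p] == s for p, s in zip(positions, subs)):
                    continue
                variant = list(barcode)
                for p, s in zip(positions, subs):
                    variant[p] = s
                out.add("".join(variant))
    return out


@dataclass
class BarcodeIndex:
    """Strain -> barcode mapping with a mismatch-tolerant lookup table."""

    barcodes: dict[str, str]                 # strain_id -> barcode
    max_mismatch: int = 2
    up_flank: str = UP_FLANK
    down_flank: str = DOWN_FLANK
    min_pairwise_distance: int = field(default=0)
    _lookup: dict[str, str] = field(default_factory=dict, repr=False)

    @property
    def strains(self) -> list[str]:
        return list(self.barcodes)


def build_index(
    barcode_table: pd.DataFrame | dict[str, str],
    max_mismatch: int = 2,
) -> BarcodeIndex:
    """Build the barcode index and its Hamming-ball lookup.

    ``barcode_table`` is a mapping or a DataFrame with strain_id/barcode
    columns.  Duplicate barcodes are a hard failure naming the offending
    strains; a minimum pairwise distance below ``2*max_mismatch + 1`` only
    warns, because assignment can then be ambiguous (such reads are counted
    as ambiguous, never misassigned).
    """
    if isinstance(barcode_table, pd.DataFrame):
        mapping = dict(zip(barcode_table["strain_id"], barcode_table["barcode"]))
    else:
        mapping = dict(barcode_table)
    for strain, bc in mapping.items():
        if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
            raise ValueError(f"strain {strain!r}: barcode {bc!r} is not 12-nt ACGT")
    series = pd.Series(mapping)
    dups = series[series.duplicated(keep=False)]
    if len(dups):
        pairs = dups.groupby(dups.values).groups
        detail = "; ".join(f"{bc}: {list(strains)}" for bc, strains in pairs.items())
        raise ValueError(f"duplicate barcodes ({detail})")

    min_dist = min_pairwise_hamming(list(mapping.values()))
    if min_dist < 2 * max_mismatch + 1:
        warnings.warn(
            f"min pairwise barcode distance {min_dist} < {2 * max_mismatch + 1}: "
            f"assignment at {max_mismatch} mismatches may be ambiguous",
            stacklevel=2,
        )
    lookup: dict[str, str] = {}
    for strain, bc in mapping.items():
        for variant in _ball(bc, max_mismatch):
            lookup[variant] = AMBIGUOUS if variant in lookup else strain
    return BarcodeIndex(
        barcodes=mapping,
        max_mismatch=max_mismatch,
        min_pairwise_distance=min_dist,
        _lookup=lookup,
    )


def find_flank(
    seq: str,
    flank: str,
    expected: int,
    max_shift: int = 2,
    max_mismatch: int = 1,
) -> int:
    """Locate a flank near its expected position; -1 if absent.

    Exact matches are preferred over 1-mismatch matches, and smaller shifts
    over larger ones.
    """
    n = len(flank)
    shifts = sorted(range(-max_shift, max_shift + 1), key=abs)
    for budget in range(max_mismatch + 1):
        for shift in shifts:
            pos = expected + shift
            if pos < 0 or pos + n > len(seq):
                continue
            window = seq[pos : pos + n]
            if budget == 0:
                if window == flank:
                    return pos
            elif hamming(window, flank) <= budget:
                return pos
    return -1


@dataclass
class CountMatrix:
    """Strains x samples barcode counts with per-sample read accounting."""

    counts: pd.DataFrame    # index strain_id, columns sample_id
    samples: pd.DataFrame   # sample_id, medium, dose_nM, time_h, replicate
    totals: pd.DataFrame    # sample_id -> assigned, ambiguous, unassigned, total

    def validate(self) -> None:
        t = self.totals
        if not (t["assigned"] + t["ambiguous"] + t["unassigned"] == t["total"]).all():
            raise AssertionError("read accounting does not conserve totals")
        if (self.counts < 0).any().any():
            raise AssertionError("negative counts")


def assign_read(
    seq: str,
    index: BarcodeIndex,
    flank_max_mismatch: int = 1,
    flank_max_shift: int = 2,
) -> str | None:
    """Assign one read: strain_id, AMBIGUOUS, or None (unassigned)."""
    up, down = index.up_flank, index.down_flank
    nu = len(up)
    pos = find_flank(seq, up, 0, flank_max_shift, flank_max_mismatch)
    if pos < 0:
        return None
    bc_start = pos + nu
    bc_end = bc_start + BARCODE_LENGTH
    if bc_end + len(down) > len(seq):
        return None
    if seq[bc_end : bc_end + len(down)] != down and (
        hamming(seq[bc_end : bc_end + len(down)], down) > flank_max_mismatch
    ):
        return None
    return index._lookup.get(seq[bc_start:bc_end])


def count_reads(
    fastq_by_sample: dict[str, str | Path],
    index: BarcodeIndex,
    sample_meta: pd.DataFrame | None = None,
    flank_max_mismatch: int = 1,
    flank_max_shift: int = 2,
) -> CountMatrix:
    """Count barcode reads per strain for each (pre-demultiplexed) sample.

    Reads whose barcode is within ``max_mismatch`` of exactly one strain are
    assigned; within the budget of two or more strains, ambiguous (and
    discarded); otherwise unassigned.  Per-sample accounting always
    satisfies assigned + ambiguous + unassigned = total.
    """
    strains = index.strains
    strain_pos = {s: i for i, s in enumerate(strains)}
    lookup = index._lookup
    up, down = index.up_flank, index.down_flank
    nu, nd = len(up), len(down)
    counts = np.zeros((len(strains), len(fastq_by_sample)), dtype=np.int64)
    totals = []
    fast_flanks = flank_max_mismatch >= 0  # fast path valid for any budget
    for s_idx, (sample, path) in enumerate(fastq_by_sample.items()):
        assigned = ambiguous = unassigned = total = 0
        with open(path) as fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    total += 1
                    # fast path: everything exact and in place
                    if (
                        seq.startswith(up)
                        and seq[nu + BARCODE_LENGTH : nu + BARCODE_LENGTH + nd] == down
                    ):
                        hit = lookup.get(seq[nu : nu + BARCODE_LENGTH])
                    else:
                        hit = assign_read(seq, index, flank_max_mismatch, flank_max_shift)
                    if hit is None:
                        unassigned += 1
                    elif hit == AMBIGUOUS:
                        ambiguous += 1
                    else:
                        counts[strain_pos[hit], s_idx] += 1
                        assigned += 1
            except ValueError as exc:
                raise ValueError(
                    f"sample {sample!r}: unreadable FASTQ record "
                    f"#{total + 1} in {path}: {exc}"
                ) from exc
        totals.append((sample, assigned, ambiguous, unassigned, total))
    counts_df = pd.DataFrame(counts, index=strains, columns=list(fastq_by_sample))
    totals_df = pd.DataFrame(
        totals, columns=["sample_id", "assigned", "ambiguous", "unassigned", "total"]
    ).set_index("sample_id")
    if sample_meta is None:
        sample_meta = pd.DataFrame({"sample_id": list(fastq_by_sample)})
    cm = CountMatrix(counts=counts_df, samples=sample_meta.reset_index(drop=True), totals=totals_df)
    cm.validate()
    return cm


@dataclass
class FitnessMatrix:
    """Strains x samples log2 fold changes relative to spike-in and t0."""

    values: pd.DataFrame
    samples: pd.DataFrame
    floor: float
    floored: pd.DataFrame  # boolean mask of floored cells


def fitness_log2fc(
    cm: CountMatrix,
    wt_strain: str,
    floor_quantile: float = 0.05,
) -> FitnessMatrix:
    """Spike-in- and t0-normalized log2 fold-change fitness.

    (1) counts are floored at the ``floor_quantile`` of the pooled time-0
    count distribution; (2) each strain's count is divided by the wild-type
    spike-in count in the same sample; (3) the ratio is divided by the
    geometric mean of the strain's time-0 ratios in the same medium and
    log2-transformed.  By construction the t0 columns of each medium
    average to zero per strain.  Depth changes cancel in the ratios.
    """
    meta = cm.samples.set_index("sample_id")
    if wt_strain not in cm.counts.index:
        raise ValueError(f"wild-type strain {wt_strain!r} not in count matrix")
    if (cm.counts.loc[wt_strain] <= 0).any():
        bad = cm.counts.columns[cm.counts.loc[wt_strain] <= 0].tolist()
        raise RuntimeError(f"spike-in failure: wild-type count is 0 in samples {bad}")
    t0_samples = meta.index[meta["time_h"] == 0].tolist()
    if not t0_samples:
        raise ValueError("no time-0 samples present")

    floor = float(np.quantile(cm.counts[t0_samples].to_numpy().ravel(), floor_quantile))
    floored = cm.counts < floor
    counts = cm.counts.clip(lower=floor)
    ratios = counts / counts.loc[wt_strain]
    log2r = np.log2(ratios)

    out = pd.DataFrame(index=cm.counts.index, columns=cm.counts.columns, dtype=float)
    for medium, samples in meta.groupby("medium").groups.items():
        samples = list(samples)
        arm_t0 = [s for s in samples if meta.loc[s, "time_h"] == 0]
        if not arm_t0:
            raise ValueError(f"medium {medium!r} has no time-0 sample")
        baseline = log2r[arm_t0].mean(axis=1)  # geometric mean in log space
        out[samples] = log2r[samples].sub(baseline, axis=0)
    return FitnessMatrix(values=out, samples=cm.samples, floor=floor, floored=floored)


def cluster_fitness(
    fm: FitnessMatrix,
    k: int,
    wt_strain: str | None = None,
    depletion_threshold: float = 0.5,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Cluster fitness profiles and annotate condition-dependent depletion.

    Hierarchical clustering with average linkage.  The default metric is
    Euclidean distance on the log2FC profiles: screens are dominated by
    neutral strains whose profiles are near-constant noise, and correlation
    between two near-constant profiles is essentially random, so a
    correlation metric cannot group the neutral class.  Euclidean distance
    keeps neutral strains together (all near the origin) while separating
    depletion patterns by shape and magnitude.  ``metric='correlation'``
    is available; constant-profile pairs then get distance 0 (both
    constant) or 1 (one constant).

    Each cluster is annotated by where its mean profile is depleted (mean
    log2FC below ``-depletion_threshold`` among post-t0 samples): only in
    minimal medium without inducer -> auxotroph-like; only in induced
    arms -> overexpression-toxic-like.
    """
    values = fm.values.drop(index=[wt_strain], errors="ignore") if wt_strain else fm.values
    if values.isna().all(axis=1).any():
        raise ValueError("fitness matrix has all-missing strain rows")
    if k > len(values):
        raise ValueError(f"k={k} exceeds {len(values)} strains")
    X = values.to_numpy(dtype=float)
    if metric == "correlation":
        sd = X.std(axis=1)
        centered = X - X.mean(axis=1, keepdims=True)
        denom = np.outer(sd, sd) * X.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = centered @ centered.T / denom
        dist = 1.0 - corr
        const = sd == 0
        dist[np.outer(const, const)] = 0.0
        dist[np.outer(const, ~const) | np.outer(~const, const)] = 1.0
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(X, metric=metric)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    meta = fm.samples.set_index("sample_id")
    post = meta.index[meta["time_h"] > 0]
    annotations = {}
    for c in np.unique(labels):
        mean_profile = values.loc[labels == c].mean(axis=0)
        depleted = set()
        for (medium, dose), samples in meta.loc[post].groupby(["medium", "dose_nM"]).groups.items():
            if mean_profile[list(samples)].mean() < -depletion_threshold:
                depleted.add((medium, float(dose)))
        if not depleted:
            ann = "neutral"
        elif all(d == 0 and m == "YNB" for m, d in depleted):
            ann = "auxotroph-like"
        elif all(d > 0 for _, d in depleted):
            ann = "overexpression-toxic-like"
        else:
            ann = "mixed:" + ",".join(f"{m}@{d:g}nM" for m, d in sorted(depleted))
        annotations[c] = ann
    return pd.DataFrame(
        {
            "strain_id": values.index,
            "cluster": labels,
            "annotation": [annotations[c] for c in labels],
        }
    ).reset_index(drop=True)
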