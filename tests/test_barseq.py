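"""Barcode index, mismatch-tolerant counting, fitness, and clustering."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import zevphen as z
from zevphen.barseq import AMBIGUOUS, assign_read, build_index, find_flank, hamming
from zevphen.config import DOWN_FLANK, UP_FLANK, SimulationConfig

from conftest import oracle_assign


@pytest.fixture(scope="module")
def index(small_panel_module):
    return build_index(small_panel_module.table[["strain_id", "barcode"]])


@pytest.fixture(scope="module")
def small_panel_module():
    cfg = SimulationConfig(n_strains=40, seed=21)
    return z.make_strain_panel(cfg)


def _read(barcode: str, filler: str = "ACGTAC") -> str:
    return UP_FLANK + barcode + DOWN_FLANK + filler


class TestBuildIndex:
    def test_index_covers_all_strains(self, index, small_panel_module):
        assert len(index.barcodes) == len(small_panel_module.table)

    def test_duplicate_barcode_names_offenders(self):
        with pytest.raises(ValueError) as err:
            build_index({"s1": "A" * 12, "s2": "A" * 12})
        assert "s1" in str(err.value) and "s2" in str(err.value)

    def test_min_distance_matches_brute_force(self, index, small_panel_module):
        barcodes = small_panel_module.table["barcode"].tolist()
        brute = min(
            hamming(a, b)
            for i, a in enumerate(barcodes)
            for b in barcodes[i + 1 :]
        )
        assert index.min_pairwise_distance == brute

    def test_close_barcodes_warn(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            build_index({"s1": "AAAAAAAAAAAA", "s2": "AAAAAAAAAAAT"})


class TestAssignment:
    def test_exact_read_assigned(self, index, small_panel_module):
        row = small_panel_module.table.iloc[0]
        assert assign_read(_read(row.barcode), index) == row.strain_id

    def test_two_mismatches_tolerated(self, index, small_panel_module):
        row = small_panel_module.table.iloc[3]
        bc = list(row.barcode)
        for pos in (2, 7):
            bc[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bc[pos]]
        assert assign_read(_read("".join(bc)), index) == row.strain_id

    def test_three_mismatches_unassigned(self, index, small_panel_module):
        row = small_panel_module.table.iloc[5]
        bc = list(row.barcode)
        for pos in (1, 5, 9):
            bc[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bc[pos]]
        assert assign_read(_read("".join(bc)), index) is None

    def test_ball_lookup_equals_exhaustive_scan(self, index, small_panel_module):
        rng = np.random.default_rng(9)
        barcodes = dict(
            zip(small_panel_module.table.strain_id, small_panel_module.table.barcode)
        )
        bases = np.array(list("ACGT"))
        for _ in range(300):
            bc = "".join(rng.choice(bases, 12))
            expected = oracle_assign(bc, barcodes)
            got = index._lookup.get(bc)
            got = {None: None, AMBIGUOUS: "AMBIGUOUS"}.get(got, got)
            assert got == expected

    def test_shifted_flank_found(self, index, small_panel_module):
        row = small_panel_module.table.iloc[2]
        read = "AC" + _read(row.barcode)  # upstream flank shifted by +2
        assert assign_read(read, index) == row.strain_id

    def test_flank_mismatch_budget(self, index, small_panel_module):
        row = small_panel_module.table.iloc[4]
        bad_up = "T" + UP_FLANK[1:]
        assert (
            assign_read(bad_up + row.barcode + DOWN_FLANK, index) == row.strain_id
        )
        very_bad = "TT" + UP_FLANK[2:]
        assert assign_read(very_bad + row.barcode + DOWN_FLANK, index) is None

    def test_find_flank_prefers_exact_and_small_shift(self):
        seq = UP_FLANK + "ACGT"
        assert find_flank(seq, UP_FLANK, 0) == 0


class TestCounting:
    def _run(self, tmp_path, cfg, panel):
        design = z.make_barseq_design(media=("SC",), n_t0=3, times={"SC": (9.0, 18.0, 36.0)})
        ab, planted = z.simulate_pool_abundances(panel, design, cfg)
        true_counts = z.simulate_barseq_run(panel, ab, cfg, tmp_path)
        index = build_index(panel.table[["strain_id", "barcode"]])
        fastqs = {s: tmp_path / f"{s}.fastq" for s in design.sample_id}
        cm = z.count_reads(fastqs, index, design)
        return design, planted, true_counts, cm

    def test_zero_error_counts_exact_and_conserved(self, tmp_path, small_panel_module):
        cfg = SimulationConfig(n_strains=40, seed=21, read_depth=30_000, per_base_error=0.0)
        _, _, true_counts, cm = self._run(tmp_path, cfg, small_panel_module)
        pd.testing.assert_frame_equal(
            cm.counts.sort_index(), true_counts.sort_index(), check_names=False
        )
        t = cm.totals
        assert (t["assigned"] + t["ambiguous"] + t["unassigned"] == t["total"]).all()
        assert (t["assigned"] == t["total"]).all()

    def test_noisy_assignments_match_oracle(self, tmp_path, small_panel_module):
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        cfg = SimulationConfig(n_strains=40, seed=22, read_depth=4000, per_base_error=0.005)
        design, _, _, cm = self._run(tmp_path, cfg, small_panel_module)
        index = build_index(small_panel_module.table[["strain_id", "barcode"]])
        barcodes = dict(
            zip(small_panel_module.table.strain_id, small_panel_module.table.barcode)
        )
        sample = design.sample_id.iloc[0]
        n_checked = 0
        with open(tmp_path / f"{sample}.fastq") as fh:
            for _t, seq, _q in FastqGeneralIterator(fh):
                got = assign_read(seq, index)
                # independent oracle: same flank contract, exhaustive scan
                pos = find_flank(seq, UP_FLANK, 0)
                expected = None
                if pos >= 0:
                    bc = seq[pos + 17 : pos + 29]
                    down = seq[pos + 29 : pos + 44]
                    if len(down) == 15 and hamming(down, DOWN_FLANK) <= 1:
                        expected = oracle_assign(bc, barcodes)
                got = {None: None, AMBIGUOUS: "AMBIGUOUS"}.get(got, got)
                assert got == expected
                n_checked += 1
        assert n_checked == 4000

    def test_truncated_fastq_names_record(self, tmp_path, small_panel_module):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n")
        index = build_index(small_panel_module.table[["strain_id", "barcode"]])
        with pytest.raises(ValueError, match="record #2"):
            z.count_reads({"s": path}, index)


class TestFitness:
    def _count_matrix(self, counts, meta):
        from zevphen.barseq import CountMatrix

        totals = pd.DataFrame(
            {
                "assigned": counts.sum(),
                "ambiguous": 0,
                "unassigned": 0,
                "total": counts.sum(),
            }
        ).rename_axis("sample_id")
        return CountMatrix(counts=counts, samples=meta, totals=totals)

    def _meta(self, samples, times):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "medium": "SC",
                "dose_nM": 0.0,
                "time_h": times,
                "replicate": 0,
            }
        )

    def test_unchanged_ratio_gives_zero(self):
        counts = pd.DataFrame(
            {"t0a": [1000, 100], "t0b": [1000, 100], "t1": [2000, 200]},
            index=["wt", "s"],
        )
        fm = z.fitness_log2fc(self._count_matrix(counts, self._meta(["t0a", "t0b", "t1"], [0.0, 0.0, 9.0])), "wt", floor_quantile=0.0)
        assert fm.values.loc["s", "t1"] == pytest.approx(0.0)

    def test_halved_ratio_gives_minus_one(self):
        # wt doubles while s is flat: s's wt-relative ratio halves
        counts = pd.DataFrame(
            {"t0": [1000, 100], "t1": [2000, 100]}, index=["wt", "s"]
        )
        fm = z.fitness_log2fc(self._count_matrix(counts, self._meta(["t0", "t1"], [0.0, 9.0])), "wt", floor_quantile=0.0)
        assert fm.values.loc["s", "t1"] == pytest.approx(-1.0)

    def test_depth_invariance(self):
        counts = pd.DataFrame(
            {"t0": [1000, 100], "t1": [800, 120]}, index=["wt", "s"]
        )
        half = (counts / 2).astype(int)
        meta = self._meta(["t0", "t1"], [0.0, 9.0])
        f1 = z.fitness_log2fc(self._count_matrix(counts, meta), "wt", floor_quantile=0.0)
        f2 = z.fitness_log2fc(self._count_matrix(half, meta), "wt", floor_quantile=0.0)
        pd.testing.assert_frame_equal(f1.values, f2.values)

    def test_t0_columns_average_zero(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(100, 10000, size=(5, 4)),
            index=["wt", "a", "b", "c", "d"],
            columns=["t0a", "t0b", "t0c", "t1"],
        )
        meta = self._meta(["t0a", "t0b", "t0c", "t1"], [0.0, 0.0, 0.0, 9.0])
        fm = z.fitness_log2fc(self._count_matrix(counts, meta), "wt", floor_quantile=0.0)
        np.testing.assert_allclose(
            fm.values[["t0a", "t0b", "t0c"]].mean(axis=1), 0.0, atol=1e-12
        )

    def test_wt_dropout_aborts(self):
        counts = pd.DataFrame({"t0": [0, 100]}, index=["wt", "s"])
        with pytest.raises(RuntimeError, match="spike-in"):
            z.fitness_log2fc(self._count_matrix(counts, self._meta(["t0"], [0.0])), "wt")


class TestClusterFitness:
    def test_all_neutral_pool_single_dominant_cluster(self):
        rng = np.random.default_rng(1)
        from zevphen.barseq import FitnessMatrix

        values = pd.DataFrame(
            rng.normal(0, 0.03, size=(40, 6)),
            index=[f"s{i}" for i in range(40)],
            columns=[f"c{i}" for i in range(6)],
        )
        meta = pd.DataFrame(
            {
                "sample_id": values.columns,
                "medium": "SC",
                "dose_nM": [0.0, 0.0, 0.0, 100.0, 100.0, 100.0],
                "time_h": [0.0, 9.0, 18.0, 0.0, 9.0, 18.0],
                "replicate": 0,
            }
        )
        fm = FitnessMatrix(values, meta, floor=0.0, floored=values < np.inf)
        out = z.cluster_fitness(fm, k=2)
        dominant = out["cluster"].value_counts().idxmax()
        members = out[out.cluster == dominant].strain_id
        assert len(members) >= 35
        assert values.loc[members].abs().mean().mean() < 0.1
        assert (out[out.cluster == dominant].annotation == "neutral").all()

    def test_duplicated_strains_co_cluster(self):
        from zevphen.barseq import FitnessMatrix

        values = pd.DataFrame(
            [[0.0, -1.0, -2.0]] * 2 + [[0.0, 0.1, 0.0]] * 2,
            index=["a1", "a2", "b1", "b2"],
            columns=["t0", "t1", "t2"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["t0", "t1", "t2"],
                "medium": "SC",
                "dose_nM": 100.0,
                "time_h": [0.0, 9.0, 18.0],
                "replicate": 0,
            }
        )
        fm = FitnessMatrix(values, meta, floor=0.0, floored=values < np.inf)
        out = z.cluster_fitness(fm, k=2).set_index("strain_id")
        assert out.loc["a1", "cluster"] == out.loc["a2", "cluster"]
        assert out.loc["b1", "cluster"] == out.loc["b2", "cluster"]
        assert out.loc["a1", "cluster"] != out.loc["b1", "cluster"]

    def test_planted_patterns_recovered(self, tmp_path):
        pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(
            n_strains=100, seed=3, read_depth=100_000, per_base_error=0.0
        )
        panel = z.make_strain_panel(cfg)
        design = z.make_barseq_design()
        ab, _ = z.simulate_pool_abundances(panel, design, cfg)
        true_counts = z.simulate_barseq_run(panel, ab, cfg, tmp_path)
        index = build_index(panel.table[["strain_id", "barcode"]])
        cm = z.count_reads(
            {s: tmp_path / f"{s}.fastq" for s in design.sample_id}, index, design
        )
        fm = z.fitness_log2fc(cm, panel.wt_strain)
        out = z.cluster_fitness(fm, k=3, wt_strain=panel.wt_strain)
        truth_tab = panel.table.set_index("strain_id").loc[out.strain_id]
        truth = np.where(
            truth_tab.aux_flag, "aux",
            np.where(truth_tab.toxicity_effect > 0, "tox", "neut"),
        )
        assert adjusted_rand_score(truth, out.cluster) >= 0.9
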