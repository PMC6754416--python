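import numpy as np
import pandas as pd
import pytest

from screfine import (
    CountMatrix,
    filter_identifications,
    normalize_counts,
    read_counts,
    write_counts,
)
from screfine.simulate import SimConfig, simulate_counts

from conftest import make_matrix


def _write_fixture(tmp_path, counts_text, design_text):
    cpath = tmp_path / "counts.tsv"
    dpath = tmp_path / "design.tsv"
    cpath.write_text(counts_text)
    dpath.write_text(design_text)
    return cpath, dpath


DESIGN_6 = (
    "run\tcondition\n"
    "r1\tHG\nr2\tHG\nr3\tHG\nr4\tGD\nr5\tGD\nr6\tGD\n"
)


class TestReadCounts:
    def test_roundtrip_of_written_fixture(self, tmp_path):
        counts = (
            "protein_id\tr1\tr2\tr3\tr4\tr5\tr6\n"
            "P1\t1\t2\t3\t4\t5\t6\n"
            "P2\t0\t0\t1\t2\t0\t3\n"
            "P3\t10\t12\t9\t30\t28\t33\n"
        )
        m = read_counts(*_write_fixture(tmp_path, counts, DESIGN_6))
        assert len(m) == 3
        assert m.conditions == ("HG", "GD")
        assert m.runs("HG") == ["r1", "r2", "r3"]
        assert m.counts.loc["P3", "r4"] == 30

    def test_negative_count_rejected_with_location(self, tmp_path):
        counts = (
            "protein_id\tr1\tr2\tr3\tr4\tr5\tr6\n"
            "P1\t1\t2\t3\t4\t5\t6\n"
            "P2\t0\t-1\t1\t2\t0\t3\n"
        )
        with pytest.raises(ValueError, match="P2.*r2"):
            read_counts(*_write_fixture(tmp_path, counts, DESIGN_6))

    def test_unknown_run_in_design_rejected(self, tmp_path):
        counts = "protein_id\tr1\tr2\tr3\tr4\tr5\tr6\nP1\t1\t2\t3\t4\t5\t6\n"
        bad_design = DESIGN_6 + "r9\tHG\n"
        with pytest.raises(ValueError, match="r9"):
            read_counts(*_write_fixture(tmp_path, counts, bad_design))

    def test_single_replicate_condition_rejected(self, tmp_path):
        counts = "protein_id\tr1\tr2\tr3\nP1\t1\t2\t3\n"
        design = "run\tcondition\nr1\tHG\nr2\tHG\nr3\tGD\n"
        with pytest.raises(ValueError, match="fewer than two runs"):
            read_counts(*_write_fixture(tmp_path, counts, design))

    def test_decoy_prefix_and_keratin_description_flagged(self, tmp_path):
        counts = (
            "protein_id\tdescription\tr1\tr2\tr3\tr4\tr5\tr6\n"
            "P1\tsome protein\t1\t2\t3\t4\t5\t6\n"
            "rev_P2\treversed\t1\t1\t1\t1\t1\t1\n"
            "P3\tKeratin type II\t5\t5\t5\t5\t5\t5\n"
        )
        m = read_counts(*_write_fixture(tmp_path, counts, DESIGN_6))
        assert m.meta.loc["rev_P2", "is_decoy"]
        assert m.meta.loc["P3", "is_contaminant"]
        assert not m.meta.loc["P1", "is_decoy"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_write_read_roundtrip_on_simulated_matrices(self, tmp_path, seed):
        matrix, _ = simulate_counts(SimConfig(n_proteins=50, seed=seed))
        write_counts(matrix, tmp_path / "c.tsv", tmp_path / "d.tsv")
        back = read_counts(tmp_path / "c.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(
            back.counts, matrix.counts, check_dtype=False
        )
        pd.testing.assert_series_equal(back.design, matrix.design)


class TestFilterIdentifications:
    def test_published_filtering_arithmetic(self):
        # 2,819 identifications, 40 keratin contaminants, 254 decoys
        n, n_ker, n_dec = 2819, 40, 254
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(n, 6)).astype(float)
        meta = pd.DataFrame(
            {
                "description": "",
                "is_contaminant": [True] * n_ker + [False] * (n - n_ker),
                "is_decoy": [False] * n_ker + [True] * n_dec
                + [False] * (n - n_ker - n_dec),
            },
            index=pd.Index([f"P{i}" for i in range(n)], name="protein_id"),
        )
        m = make_matrix(counts, meta=meta)
        kept, summary = filter_identifications(m)
        assert summary.n_kept == len(kept) == 2525
        assert summary.n_contaminant == 40
        assert summary.n_decoy == 254

    def test_no_flags_is_identity(self, toy_matrix):
        kept, summary = filter_identifications(toy_matrix)
        assert len(kept) == len(toy_matrix)
        assert summary.n_contaminant == summary.n_decoy == 0
        pd.testing.assert_frame_equal(kept.counts, toy_matrix.counts)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_partition_is_exact_on_random_flags(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        counts = rng.integers(0, 30, size=(n, 4)).astype(float)
        meta = pd.DataFrame(
            {
                "is_contaminant": rng.random(n) < 0.1,
                "is_decoy": rng.random(n) < 0.15,
            },
            index=pd.Index([f"P{i}" for i in range(n)], name="protein_id"),
        )
        m = make_matrix(counts, meta=meta)
        kept, s = filter_identifications(m)
        # brute-force recount over the flags (contaminant takes precedence)
        exp_cont = int(meta["is_contaminant"].sum())
        exp_dec = int((meta["is_decoy"] & ~meta["is_contaminant"]).sum())
        assert s.n_contaminant == exp_cont
        assert s.n_decoy == exp_dec
        assert s.n_kept + s.n_contaminant + s.n_decoy == s.n_input == n


class TestNormalizeCounts:
    def test_equal_totals_unchanged(self):
        m = make_matrix([[1, 2, 3, 4], [9, 8, 7, 6]])  # all totals 10
        out = normalize_counts(m)
        np.testing.assert_allclose(out.counts, m.counts)

    def test_scale_factors_follow_grand_mean(self):
        # run totals 100, 200, 150, 150 -> grand mean 150 ->
        # factors 1.5, 0.75, 1, 1
        counts = np.array([[60, 120, 90, 90], [40, 80, 60, 60]], dtype=float)
        out = normalize_counts(make_matrix(counts))
        np.testing.assert_allclose(
            out.counts.to_numpy()[:, 0], counts[:, 0] * 1.5
        )
        np.testing.assert_allclose(
            out.counts.to_numpy()[:, 1], counts[:, 1] * 0.75
        )
        np.testing.assert_allclose(out.counts.to_numpy()[:, 2:], counts[:, 2:])

    def test_totals_equalized_and_idempotent(self, toy_matrix):
        out = normalize_counts(toy_matrix)
        totals = out.counts.sum(axis=0)
        np.testing.assert_allclose(totals, totals.iloc[0])
        again = normalize_counts(out)
        np.testing.assert_allclose(again.counts, out.counts, atol=1e-9)

    def test_zero_total_run_rejected(self):
        m = make_matrix([[0, 2, 3, 4], [0, 8, 7, 6]])
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(m)


class TestCountMatrixValidation:
    def test_duplicate_protein_ids_rejected(self):
        frame = pd.DataFrame(
            np.ones((2, 4)),
            index=["P1", "P1"],
            columns=["a1", "a2", "b1", "b2"],
        )
        design = pd.Series(
            ["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"]
        )
        with pytest.raises(ValueError, match="duplicated"):
            CountMatrix(frame, design)

    def test_three_conditions_rejected(self):
        frame = pd.DataFrame(
            np.ones((2, 6)), index=["P1", "P2"],
            columns=[f"r{i}" for i in range(6)],
        )
        design = pd.Series(
            ["A", "A", "B", "B", "C", "C"],
            index=[f"r{i}" for i in range(6)],
        )
        with pytest.raises(ValueError, match="two conditions"):
            CountMatrix(frame, design)

    def test_missing_value_rejected(self):
        counts = np.ones((2, 4))
        counts[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing count"):
            make_matrix(counts)
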