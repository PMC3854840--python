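import numpy as np
import pandas as pd
import pytest

from mitospectra.align import AlignmentSet
from mitospectra.snv import (
    SNVCallParams,
    add_annotations,
    call_snvs,
    normalize_runs,
    threshold_somatic,
)


def make_alignment(n_reads, rl, L, ref_start=0):
    """A trivial AlignmentSet: every read fully aligned at ref_start, + strand."""
    return AlignmentSet(
        stringency="high",
        accepted=np.ones(n_reads, dtype=bool),
        strand=np.zeros(n_reads, dtype=np.uint8),
        ref_start=np.full(n_reads, ref_start, dtype=np.int64),
        read_start=np.zeros(n_reads, dtype=np.int32),
        length=np.full(n_reads, rl, dtype=np.int32),
        matches=np.full(n_reads, rl, dtype=np.int32),
        columns=np.full(n_reads, rl, dtype=np.int32),
        L=L,
    )


@pytest.fixture()
def scenario(rng):
    """20 reads of 60 bp over a 200 bp consensus, all matching by default."""
    L, rl, n = 200, 60, 20
    cons = rng.integers(0, 4, L).astype(np.uint8)
    seqs = np.tile(cons[:rl], (n, 1))
    quals = np.full((n, rl), 38, dtype=np.int8)
    aln = make_alignment(n, rl, L)
    aln.read_length = rl
    return cons, seqs, quals, aln


def variant_at(seqs, read, pos, cons):
    seqs = seqs.copy()
    seqs[read, pos] = (cons[pos] + 1) % 4
    return seqs


class TestQualityFilters:
    def test_clean_variant_counted(self, scenario):
        cons, seqs, quals, aln = scenario
        seqs = variant_at(seqs, 0, 30, cons)
        quals = quals.copy()
        quals[0, 30] = 34
        out = call_snvs(aln, seqs, quals, cons)
        row = out.table[out.table["pos"] == 31]
        assert len(row) == 1 and row["count"].iloc[0] == 1

    def test_central_quality_boundary_is_strict(self, scenario):
        """A variant base at exactly Q33 is rejected (filter is > Q33)."""
        cons, seqs, quals, aln = scenario
        seqs = variant_at(seqs, 0, 30, cons)
        quals = quals.copy()
        quals[0, 30] = 33
        out = call_snvs(aln, seqs, quals, cons)
        assert not (out.table["pos"] == 31).any()
        quals[0, 30] = 34
        out = call_snvs(aln, seqs, quals, cons)
        assert (out.table["pos"] == 31).any()

    def test_window_mean_boundary_is_strict(self, scenario):
        """Window mean exactly Q30 fails; just above passes."""
        cons, seqs, quals, aln = scenario
        seqs = variant_at(seqs, 0, 30, cons)
        quals = quals.copy()
        quals[0, :] = 30
        quals[0, 30] = 34  # window 25..35 mean = (10*30 + 34)/11 > 30 -> passes
        out = call_snvs(aln, seqs, quals, cons)
        assert (out.table["pos"] == 31).any()
        quals[0, 30] = 30  # but now the central filter fails anyway
        quals[0, :] = 30  # mean exactly 30
        out = call_snvs(aln, seqs, quals, cons)
        assert not (out.table["pos"] == 31).any()
        # mean exactly 30 with a high central base: 34 + 10*x = 330 -> x = 29.6
        quals[0, :] = 30
        quals[0, 30] = 34
        quals[0, 25] = 26  # window sum = 34 + 26 + 9*30 = 330, mean exactly 30
        out = call_snvs(aln, seqs, quals, cons)
        assert not (out.table["pos"] == 31).any()

    def test_other_mismatch_rule_boundary(self, scenario):
        """Three mismatches in one 11 bp window: each sees exactly 2 others,
        so all are counted (<= 2 passes); four mismatches kill them all."""
        cons, seqs, quals, aln = scenario
        s3 = seqs.copy()
        for p in (28, 30, 32):
            s3 = variant_at(s3, 0, p, cons)
        out = call_snvs(aln, s3, quals, cons)
        assert set(out.table["pos"]) == {29, 31, 33}
        s4 = variant_at(s3, 0, 34, cons)
        # now 30 sees {28, 32, 34} and 32 sees {28, 30, 34}: three others
        # each -> rejected; the outer sites still see only two -> kept
        out = call_snvs(aln, s4, quals, cons)
        assert set(out.table["pos"]) == {29, 35}

    def test_window_clips_at_read_ends(self, scenario):
        cons, seqs, quals, aln = scenario
        seqs = variant_at(seqs, 0, 0, cons)  # first read base
        out = call_snvs(aln, seqs, quals, cons)
        assert (out.table["pos"] == 1).any()

    def test_depth_counts_all_alleles(self, scenario):
        cons, seqs, quals, aln = scenario
        seqs = variant_at(seqs, 0, 30, cons)
        out = call_snvs(aln, seqs, quals, cons)
        row = out.table[out.table["pos"] == 31].iloc[0]
        assert row["depth"] == 20
        assert row["frequency"] == pytest.approx(1 / 20)

    def test_tightening_thresholds_is_monotone(self, scenario, rng):
        cons, seqs, quals, aln = scenario
        seqs = seqs.copy()
        quals = rng.integers(28, 41, quals.shape).astype(np.int8)
        for i in range(10):
            seqs = variant_at(seqs, i, int(rng.integers(0, 60)), cons)
        base = call_snvs(aln, seqs, quals, cons).table["count"].sum()
        for params in (
            SNVCallParams(q_central=36),
            SNVCallParams(q_window=34),
            SNVCallParams(max_other_mismatches=0),
        ):
            tight = call_snvs(aln, seqs, quals, cons, params=params)
            assert tight.table["count"].sum() <= base

    def test_excluded_reads_do_not_contribute(self, scenario):
        cons, seqs, quals, aln = scenario
        seqs = variant_at(seqs, 0, 30, cons)
        exclude = np.zeros(len(seqs), dtype=bool)
        exclude[0] = True
        out = call_snvs(aln, seqs, quals, cons, exclude=exclude)
        assert not (out.table["pos"] == 31).any()
        assert out.table.empty


class TestThreshold:
    def _table(self, freqs):
        return pd.DataFrame(
            {
                "pos": np.arange(1, len(freqs) + 1),
                "ref": "A",
                "alt": "G",
                "count": 1,
                "depth": 1,
                "frequency": freqs,
            }
        )

    def test_strict_threshold(self):
        out = threshold_somatic(self._table([0.009, 0.010, 0.011, 0.5]))
        assert out["frequency"].tolist() == [0.009]

    def test_custom_threshold(self):
        out = threshold_somatic(self._table([0.04, 0.06]), threshold=0.05)
        assert out["frequency"].tolist() == [0.04]


class TestAnnotations:
    def test_region_and_change(self, annot):
        df = pd.DataFrame(
            {"pos": [3243, 100], "ref": ["A", "C"], "alt": ["G", "A"],
             "count": [1, 1], "depth": [10, 10], "frequency": [0.1, 0.1]}
        )
        out = add_annotations(df, annot)
        assert out["region"].tolist() == ["coding", "control"]
        assert out["change"].tolist() == ["A>G", "C>A"]
        assert out["transition"].tolist() == [True, False]


class TestRunNormalization:
    def _tables(self, shift=0.0):
        a = pd.DataFrame(
            {"pos": [100, 200, 300], "ref": "G", "alt": "A",
             "count": 1, "depth": 1000,
             "frequency": [1e-4, 2e-4, 3e-4],
             "region": ["coding"] * 3, "change": ["G>A"] * 3}
        )
        b = a.copy()
        b["frequency"] = b["frequency"] + shift
        return {"s1": a, "s2": b}

    def test_identical_runs_zero_offsets(self):
        tables, norm = normalize_runs(self._tables(), {"s1": "r1", "s2": "r2"})
        assert np.allclose(norm.offsets["offset"].abs(), 0.0)

    def test_uniform_shift_recovered(self):
        tables, norm = normalize_runs(self._tables(1e-5), {"s1": "r1", "s2": "r2"})
        off = norm.offsets.set_index("run")["offset"]
        assert off["r1"] - off["r2"] == pytest.approx(1e-5)
        # matched means equal after correction
        assert tables["s1"]["frequency"].mean() == pytest.approx(
            tables["s2"]["frequency"].mean()
        )

    def test_per_base_change_equalizes_coding_means(self):
        tabs = self._tables(5e-5)
        tables, norm = normalize_runs(
            tabs, {"s1": "r1", "s2": "r2"}, mode="per_base_change"
        )
        m1 = tables["s1"].loc[tables["s1"]["change"] == "G>A", "frequency"].mean()
        m2 = tables["s2"].loc[tables["s2"]["change"] == "G>A", "frequency"].mean()
        assert m1 == pytest.approx(m2)

    def test_single_run_identity(self):
        tabs = self._tables(1e-5)
        tables, norm = normalize_runs(tabs, {"s1": "r1", "s2": "r1"})
        pd.testing.assert_frame_equal(tables["s1"], tabs["s1"])

    def test_multiplicative_mode(self):
        tabs = self._tables()
        tabs["s2"]["frequency"] *= 2
        tables, norm = normalize_runs(
            tabs, {"s1": "r1", "s2": "r2"}, multiplicative=True
        )
        assert tables["s1"]["frequency"].mean() == pytest.approx(
            tables["s2"]["frequency"].mean()
        )
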