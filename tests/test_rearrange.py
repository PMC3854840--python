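import numpy as np
import pandas as pd
import pytest

from mitospectra.align import ReferenceIndex
from mitospectra.reference import CoordinateMap, encode_seq, revcomp_codes
from mitospectra.rearrange import (
    BreakpointConfig,
    QuantWindows,
    annotate_breakpoint_repeats,
    call_breakpoint,
    calls_to_dataframe,
    classify_calls,
    dotplot_downsample,
    junction_aperture,
    quantify_rearrangements,
)

from oracles import exhaustive_split


@pytest.fixture(scope="module")
def small_index(small_genome):
    return ReferenceIndex(small_genome, 15)


@pytest.fixture(scope="module")
def alt_index(genome):
    return ReferenceIndex(genome.rotated(), 15)


class TestCallBreakpoint:
    def test_planted_two_segment_read(self, small_genome, small_index):
        # read bases 1-50 from x..x+49 and 51-100 from y..y+49 (0-based x, y)
        x, y = 200, 900
        s = small_genome.sequence
        read = encode_seq(s[x : x + 50] + s[y : y + 50])
        c = call_breakpoint(read, small_index)
        assert c is not None
        # 1-based: 5' segment ends at x+50, 3' starts at y+1 (up to chance
        # micro-extension across the junction, bounded by the overlap field)
        assert c.b5 - c.overlap <= x + 50 <= c.b5 + 5
        assert c.b3 <= y + 1 <= c.b3 + c.overlap + 1
        assert c.canonical and c.sense == "+"

    def test_contiguous_read_none(self, small_genome, small_index):
        read = encode_seq(small_genome.sequence[400:500])
        assert call_breakpoint(read, small_index) is None

    def test_common_deletion_clonal_pair(self, genome, alt_index):
        """Reads across the common-deletion junction yield one clonal
        (b5, b3) pair mapping to CRS (8482, 13447) across the 13 bp repeat."""
        cm = CoordinateMap()
        s = genome.sequence
        calls = set()
        for flank in (20, 35, 50, 65, 80):
            read = s[8482 - flank : 8482] + s[13459 : 13459 + 100 - flank]
            c = call_breakpoint(encode_seq(read), alt_index)
            assert c is not None
            calls.add((cm.alt_to_crs(c.b5), cm.alt_to_crs(c.b3)))
        assert calls == {(8482, 13447)}

    def test_reverse_strand_same_junction(self, genome, alt_index):
        cm = CoordinateMap()
        s = genome.sequence
        read = encode_seq(s[8482 - 50 : 8482] + s[13459 : 13459 + 50])
        c = call_breakpoint(revcomp_codes(read), alt_index)
        assert (cm.alt_to_crs(c.b5), cm.alt_to_crs(c.b3)) == (8482, 13447)
        assert c.sense == "-"

    def test_short_read_rejected(self, small_index):
        assert call_breakpoint(np.zeros(20, dtype=np.uint8), small_index) is None

    def test_matches_exhaustive_oracle_small(self, small_genome, small_index, rng):
        doubled = np.concatenate([small_genome.codes] * 2)
        L = small_genome.L
        agree = 0
        for i in range(60):
            kind = i % 3
            if kind == 0:  # junction read
                x, y = rng.integers(0, L, 2)
                s = int(rng.integers(20, 81))
                read = np.concatenate(
                    [doubled[x : x + s], doubled[y : y + 100 - s]]
                )
            elif kind == 1:  # contiguous
                x = int(rng.integers(0, L))
                read = doubled[x : x + 100].copy()
            else:  # random
                read = rng.integers(0, 4, 100).astype(np.uint8)
            got = call_breakpoint(read, small_index)
            exp = exhaustive_split(read, doubled, L)
            if exp is None:
                assert got is None
            else:
                assert got is not None
                assert (got.b5 - 1, got.b3 - 1) == (exp[0], exp[1])
            agree += 1
        assert agree == 60


class TestQuantification:
    def _df(self, rows):
        cm = CoordinateMap()
        recs = []
        for b5c, b3c, canonical in rows:
            b5a, b3a = cm.crs_to_alt(b5c), cm.crs_to_alt(b3c)
            recs.append(
                {"read_index": 0, "b5_alt": b5a, "b3_alt": b3a, "sense": "+",
                 "canonical": b5a < b3a, "overlap": 0, "matches": 100,
                 "multi_segment": False, "b5_crs": b5c, "b3_crs": b3c}
            )
        return pd.DataFrame(recs)

    def test_frequency_arithmetic(self):
        df = self._df([(8482, 13447, True)] * 100)
        q = quantify_rearrangements(df, 100_000, 16569)
        assert q.counts["common_deletion"] == 100
        assert q.frequencies["common_deletion"] == pytest.approx(1.0e-3)

    def test_chimera_subtraction(self):
        rows = [(8482, 13447, True)] * 100  # common (also in major window)
        rows += [(6000, 12000, True)] * 20  # other canonical major-arc
        rows += [(12000, 6000, False)] * 5  # reverse orientation (chimeras)
        df = self._df(rows)
        q = quantify_rearrangements(df, 10_000, 16569)
        assert q.counts["major_arc_window"] == 120
        assert q.counts["chimera_window"] == 5
        assert q.counts["major_arc"] == 15
        assert q.frequencies["major_arc"] == pytest.approx(1.5e-3)

    def test_major_arc_floor_at_zero(self):
        df = self._df([(12000, 6000, False)] * 10)
        q = quantify_rearrangements(df, 1000, 16569)
        assert q.counts["major_arc"] == 0

    def test_windows_mutually_exclusive(self, rng):
        rows = []
        for _ in range(300):
            b5, b3 = sorted(rng.integers(1, 16570, 2))
            if b5 == b3:
                continue
            rows.append((int(b5), int(b3), True))
            rows.append((int(b3), int(b5), False))
        df = classify_calls(self._df(rows), 16569)
        counted = df["class"].isin(
            ["common_deletion", "major_arc_window", "chimera_window", "crm", "crd"]
        )
        # each call lands in exactly one class label
        assert df["class"].notna().all()
        q = quantify_rearrangements(df, 1000, 16569)
        exclusive = (
            q.counts["common_deletion"] + q.counts["major_arc"]
            + q.counts["chimera_window"] + q.counts["crm"] + q.counts["crd"]
        )
        assert exclusive <= len(df)
        # common window calls are excluded from major_arc by subtraction
        assert q.counts["major_arc"] == max(
            0,
            q.counts["major_arc_window"] - q.counts["common_deletion"]
            - q.counts["chimera_window"],
        )

    def test_crm_window_wraps_origin(self):
        # tandem-duplication junction m.16509_22dup: b5 CRS 22, b3 CRS 16509
        df = self._df([(22, 16509, False)])
        df = classify_calls(df, 16569)
        assert df["class"].iloc[0] == "crm"
        # a small canonical deletion inside the window is not a CRM
        df2 = classify_calls(self._df([(16500, 16560, True)]), 16569)
        assert df2["class"].iloc[0] != "crm"

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            quantify_rearrangements(self._df([]), 0.0, 16569)

    def test_empty_set_all_zero(self):
        q = quantify_rearrangements(self._df([]), 1000.0, 16569)
        assert all(v == 0 for v in q.counts.values())

    def test_aperture_values(self):
        assert junction_aperture(None, 100, 15) == 71
        assert junction_aperture(None, 100, 20) == 61
        assert junction_aperture(30, 100, 15) == 0  # short tandem unit


class TestRepeatAnnotation:
    def test_common_only_set_fraction_one(self, genome, alt_index):
        s = genome.sequence
        reads = [
            encode_seq(s[8482 - f : 8482] + s[13459 : 13459 + 100 - f])
            for f in (30, 50, 70)
        ]
        calls = [call_breakpoint(r, alt_index) for r in reads]
        cm = CoordinateMap()
        df = classify_calls(calls_to_dataframe(calls, cm), genome.L)
        ann, fractions = annotate_breakpoint_repeats(df, genome.rotated())
        assert set(ann["repeat_len"]) == {13}
        assert fractions["common_deletion"] == 1.0

    def test_repeat_free_junction_fraction_zero(self, small_genome, small_index):
        # find a junction with no flanking repeat on the small genome
        from mitospectra.reference import find_flanking_direct_repeat

        s = small_genome.sequence
        target = None
        for x in range(100, 400):
            if find_flanking_direct_repeat(small_genome, x, x + 700, min_len=1) is None:
                target = x
                break
        assert target is not None
        read = encode_seq(s[target - 50 : target] + s[target + 699 : target + 749])
        c = call_breakpoint(read, small_index)
        cm = CoordinateMap(pivot=1, L=small_genome.L)
        df = classify_calls(calls_to_dataframe([c], cm), small_genome.L)
        ann, fractions = annotate_breakpoint_repeats(df, small_genome)
        assert (ann["repeat_len"] < 3).all()


class TestDotplot:
    def _sample(self, n):
        return pd.DataFrame(
            {"b5_alt": np.arange(n), "b3_alt": np.arange(n) + 500,
             "canonical": [True] * n}
        )

    def test_single_sample_no_reduction(self):
        out = dotplot_downsample({"a": (self._sample(100), 5e4)}, seed=1)
        assert len(out["a"]) == 100

    def test_ratio_arithmetic(self):
        out = dotplot_downsample(
            {"a": (self._sample(100), 5e4), "b": (self._sample(4000), 1e5)}, seed=1
        )
        assert len(out["b"]) == 2000

    def test_seeded_determinism(self):
        samples = {"a": (self._sample(100), 5e4), "b": (self._sample(4000), 1e5)}
        o1 = dotplot_downsample(samples, seed=7)
        o2 = dotplot_downsample(samples, seed=7)
        pd.testing.assert_frame_equal(o1["b"], o2["b"])
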