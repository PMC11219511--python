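import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylrad.digestion import TagFragment
from methylrad.io import FormatError
from methylrad.quantification import (
    CountMatrix,
    count_tags,
    filter_sites,
    import_alignment_counts,
    methylated_site_counts,
    methylation_level,
    methylation_summary,
    reverse_complement,
    rpm_normalize,
)


def frag(site_id, seq):
    return TagFragment(site_id, 0, len(seq), seq)


@pytest.fixture
def two_fragments():
    return [
        frag("f1", "ACGTACGTACGTACGTACGTACGTACGTACGT"),
        frag("f2", "TTTTCCCCGGGGAAAATTTTCCCCGGGGAAAA"),
    ]


class TestCountTags:
    def test_exact_copies_counted(self, two_fragments):
        reads = {"A": [two_fragments[0].sequence] * 5}
        matrix = count_tags(reads, two_fragments)
        assert matrix.counts.loc["f1", "A"] == 5
        assert matrix.counts.loc["f2", "A"] == 0

    def test_reverse_complement_counted(self, two_fragments):
        reads = {"A": [reverse_complement(two_fragments[1].sequence)]}
        matrix = count_tags(reads, two_fragments)
        assert matrix.counts.loc["f2", "A"] == 1

    def test_ambiguous_read_discarded_and_tallied(self):
        shared = "A" * 32
        frags = [frag("f1", shared), frag("f2", shared)]
        matrix = count_tags({"A": [shared]}, frags)
        assert matrix.counts["A"].sum() == 0
        assert matrix.discards.loc["A", "ambiguous"] == 1

    def test_unmatched_read_tallied(self, two_fragments):
        matrix = count_tags({"A": ["G" * 32]}, two_fragments)
        assert matrix.discards.loc["A", "unmatched"] == 1

    def test_one_mismatch_recovered_with_tolerance(self, two_fragments):
        mutated = "C" + two_fragments[0].sequence[1:]
        assert count_tags({"A": [mutated]}, two_fragments) \
            .counts.loc["f1", "A"] == 0
        assert count_tags({"A": [mutated]}, two_fragments, max_mismatch=1) \
            .counts.loc["f1", "A"] == 1

    def test_duplicate_site_ids_rejected(self, two_fragments):
        frags = two_fragments + [frag("f1", "G" * 32)]
        with pytest.raises(ValueError, match="duplicate"):
            count_tags({"A": []}, frags)


class TestFilterSites:
    def test_threshold_rule(self):
        counts = pd.DataFrame({"A": [3, 2], "B": [0, 2]},
                              index=["keep", "drop"])
        kept = filter_sites(CountMatrix(counts))
        assert kept.site_ids == ["keep"]

    def test_all_zero_matrix_empties(self):
        counts = pd.DataFrame({"A": [0, 0], "B": [0, 0]}, index=["s1", "s2"])
        assert filter_sites(CountMatrix(counts)).site_ids == []

    def test_matches_row_max_oracle_and_idempotent(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 6, size=(80, 5)),
                              index=[f"s{i}" for i in range(80)])
        kept = filter_sites(CountMatrix(counts))
        oracle = [f"s{i}" for i in range(80)
                  if max(counts.iloc[i]) >= 3]
        assert kept.site_ids == oracle
        assert filter_sites(kept).counts.equals(kept.counts)


class TestRpmNormalize:
    def test_formula(self):
        counts = pd.DataFrame({"A": [1], "B": [250]}, index=["s1"])
        rpm = rpm_normalize(CountMatrix(counts),
                            {"A": 1_000_000, "B": 5_000_000})
        assert rpm.values.loc["s1", "A"] == pytest.approx(1.0)
        assert rpm.values.loc["s1", "B"] == pytest.approx(50.0)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 50, size=(30, 6)) + 1)
        rpm = rpm_normalize(CountMatrix(counts))
        assert np.allclose(rpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_scale_free_in_each_sample(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(rng.integers(0, 50, size=(30, 3)) + 1,
                              columns=["A", "B", "C"])
        totals = counts.sum(axis=0)
        rpm1 = rpm_normalize(CountMatrix(counts), totals)
        scaled = counts.copy()
        scaled["B"] *= 7
        totals2 = totals.copy()
        totals2["B"] *= 7
        rpm2 = rpm_normalize(CountMatrix(scaled), totals2)
        assert np.allclose(rpm1.values["B"], rpm2.values["B"])

    def test_zero_total_rejected(self):
        counts = pd.DataFrame({"A": [0]}, index=["s1"])
        with pytest.raises(ValueError, match="total"):
            rpm_normalize(CountMatrix(counts))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=1000),
                    min_size=2, max_size=30).filter(lambda v: sum(v) > 0))
    def test_any_nonzero_column_conserves_a_million(self, column):
        counts = pd.DataFrame({"A": column})
        rpm = rpm_normalize(CountMatrix(counts))
        assert rpm.values["A"].sum() == pytest.approx(1e6)


class TestMethylationLevels:
    def test_counts_by_context(self):
        counts = pd.DataFrame({"A": [0, 2, 5]}, index=["s1", "s2", "s3"])
        ctx = {"s1": "CG", "s2": "CG", "s3": "CG"}
        out = methylated_site_counts(CountMatrix(counts), ctx)
        assert out.loc["A", "CG"] == 2

    def test_all_zero_counts(self):
        counts = pd.DataFrame({"A": [0, 0]}, index=["s1", "s2"])
        out = methylated_site_counts(CountMatrix(counts),
                                     {"s1": "CG", "s2": "CHG"})
        assert out.loc["A"].tolist() == [0, 0]

    def test_matches_nonzero_oracle(self):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(rng.integers(0, 4, size=(40, 5)),
                              index=[f"s{i}" for i in range(40)])
        ctx = {f"s{i}": ("CG" if i % 3 == 0 else "CHG") for i in range(40)}
        out = methylated_site_counts(CountMatrix(counts), ctx)
        for sample in counts.columns:
            for context in ("CG", "CHG"):
                expected = sum(
                    counts.loc[s, sample] > 0
                    for s in counts.index if ctx[s] == context
                )
                assert out.loc[sample, context] == expected

    def test_missing_context_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["s1"])
        with pytest.raises(KeyError):
            methylated_site_counts(CountMatrix(counts), {})

    def test_level_percentages(self):
        assert methylation_level(14.3, 69) == pytest.approx(20.7, abs=0.05)
        assert methylation_level(49.8, 201) == pytest.approx(24.8, abs=0.05)
        assert methylation_level(0, 17) == 0.0
        assert methylation_level(17, 17) == 100.0

    def test_level_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            methylation_level(1, 0)

    def test_summary_table(self):
        counts = pd.DataFrame({"A": [3, 0], "B": [1, 2]}, index=["s1", "s2"])
        summary = methylation_summary(
            CountMatrix(counts), {"s1": "CG", "s2": "CHG"},
            n_potential={"CG": 10, "CHG": 20},
        )
        row = summary.table.set_index(["sample_id", "context"])
        assert row.loc[("A", "CG"), "level_percent"] == 10.0
        assert row.loc[("B", "CHG"), "level_percent"] == 5.0


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n"


def write_sam(path, fragments, records):
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for f in fragments:
            fh.write(f"@SQ\tSN:{f.site_id}\tLN:{len(f.sequence)}\n")
        for i, (ref, mapq, seq) in enumerate(records):
            fh.write(
                f"r{i}\t0\t{ref}\t1\t{mapq}\t{len(seq)}M\t*\t0\t0\t{seq}\t"
                f"{'I' * len(seq)}\n"
            )


class TestAlignmentImport:
    def test_mapq_threshold(self, tmp_path, two_fragments):
        path = tmp_path / "a.sam"
        seq = two_fragments[0].sequence
        write_sam(path, two_fragments,
                  [("f1", 9, seq), ("f1", 10, seq), ("f1", 60, seq)])
        matrix = import_alignment_counts({"A": path}, two_fragments)
        assert matrix.counts.loc["f1", "A"] == 2

    def test_empty_alignment_zero_matrix(self, tmp_path, two_fragments):
        path = tmp_path / "a.sam"
        write_sam(path, two_fragments, [])
        matrix = import_alignment_counts({"A": path}, two_fragments)
        assert (matrix.counts.to_numpy() == 0).all()

    def test_known_record_counts(self, tmp_path, two_fragments):
        p1, p2 = tmp_path / "s1.sam", tmp_path / "s2.sam"
        seq1, seq2 = (f.sequence for f in two_fragments)
        write_sam(p1, two_fragments,
                  [("f1", 30, seq1)] * 3 + [("f2", 30, seq2)] * 2)
        write_sam(p2, two_fragments, [("f2", 30, seq2)])
        matrix = import_alignment_counts({"s1": p1, "s2": p2}, two_fragments)
        assert matrix.counts.to_numpy().tolist() == [[3, 0], [2, 1]]

    def test_unknown_reference_rejected(self, tmp_path, two_fragments):
        path = tmp_path / "a.sam"
        write_sam(path, two_fragments + [frag("rogue", "A" * 32)], [])
        with pytest.raises(FormatError, match="not in fragment set"):
            import_alignment_counts({"A": path}, two_fragments)
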