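import numpy as np
import pandas as pd
import pytest

from oxbskit.dmr_calling import DMR
from oxbskit.meth_io import (
    ContrastDesign,
    collapse_cpg_dyads,
    median_split,
    parse_region_string,
    read_dmr_bed,
    read_methratio,
    read_region_matrix,
    write_dmr_bed,
    write_methratio,
    write_region_matrix,
)


def _write(tmp_path, text, name="calls.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadMethratio:
    def test_one_based_to_internal(self, tmp_path):
        path = _write(tmp_path, "chr1\t101\t+\tCG\t0.8\t8\t10\n")
        df = read_methratio(path)
        assert df.loc[0, "pos"] == 100
        assert df.loc[0, "ratio"] == pytest.approx(0.8)

    def test_empty_file_warns(self, tmp_path):
        path = _write(tmp_path, "")
        with pytest.warns(UserWarning, match="empty"):
            df = read_methratio(path)
        assert df.empty

    def test_zero_coverage_rows_dropped(self, tmp_path):
        path = _write(tmp_path, "chr1\t101\t+\tCG\t0\t0\t0\nchr1\t201\t+\tCG\t0.5\t5\t10\n")
        df = read_methratio(path)
        assert df["pos"].tolist() == [200]

    def test_count_overflow_rejected_with_warning(self, tmp_path):
        path = _write(tmp_path, "chr1\t101\t+\tCG\t1.2\t12\t10\nchr1\t201\t+\tCG\t0.5\t5\t10\n")
        with pytest.warns(UserWarning, match="c_count > ct_count"):
            df = read_methratio(path)
        assert len(df) == 1

    def test_non_cpg_context_filtered(self, tmp_path):
        path = _write(tmp_path, "chr1\t101\t+\tCHH\t0.5\t5\t10\nchr1\t201\t+\tCG\t0.5\t5\t10\n")
        assert len(read_methratio(path)) == 1

    def test_header_detected(self, tmp_path):
        text = "chrom\tpos\tstrand\tcontext\tratio\tc_count\tct_count\nchr1\t101\t+\tCG\t0.8\t8\t10\n"
        df = read_methratio(_write(tmp_path, text))
        assert len(df) == 1

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 150],
                "strand": "+",
                "context": "CG",
                "ratio": [0.8, 0.25],
                "c_count": [8, 2],
                "ct_count": [10, 8],
            }
        )
        path = tmp_path / "rt.tsv"
        write_methratio(df, path)
        back = read_methratio(path)
        pd.testing.assert_frame_equal(
            back[["chrom", "pos", "c_count", "ct_count"]],
            df[["chrom", "pos", "c_count", "ct_count"]],
        )


def test_dyad_collapse_merges_strands():
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [100, 101],
            "strand": ["+", "-"],
            "context": "CG",
            "ratio": [0.5, 1.0],
            "c_count": [5, 10],
            "ct_count": [10, 10],
        }
    )
    out = collapse_cpg_dyads(df)
    assert len(out) == 1
    assert out.loc[0, "pos"] == 100
    assert out.loc[0, "c_count"] == 15 and out.loc[0, "ct_count"] == 20
    assert out.loc[0, "strand"] == "+"


class TestMedianSplit:
    def test_even_cohort(self):
        design = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert set(design.case_samples) == {"c", "d"}
        assert set(design.control_samples) == {"a", "b"}

    def test_ties_go_low(self):
        # median of [5, 5, 9] is 5; only the strict exceeder is "high"
        design = median_split({"a": 5, "b": 5, "c": 9})
        assert design.case_samples == ["c"]
        assert set(design.control_samples) == {"a", "b"}

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            median_split({"a": 1.0})

    def test_degenerate_contrast_rejected(self):
        with pytest.raises(ValueError):
            median_split({"a": 2.0, "b": 2.0, "c": 2.0})


def test_contrast_design_requires_both_groups():
    with pytest.raises(ValueError):
        ContrastDesign("bad", {"a": "case", "b": "case"})


class TestDmrBed:
    def _dmr(self, **kw):
        base = dict(
            chrom="chr18", start=79_461_611, end=79_461_992, mark="5mC",
            n_cpgs=12, mean_case=0.31, mean_control=0.62, mean_diff=-0.31,
            p=0.0004, q=0.0021, significant=True,
        )
        base.update(kw)
        return DMR(**base)

    def test_known_interval_written(self, tmp_path):
        # the best-performing marker region, ingested from its 1-based
        # browser string and written back 0-based half-open
        chrom, start, end = parse_region_string("chr18:79,461,612-79,461,992")
        path = tmp_path / "dmrs.bed"
        write_dmr_bed([self._dmr(chrom=chrom, start=start, end=end)], path)
        line = path.read_text().splitlines()[1].split("\t")
        assert line[:3] == ["chr18", "79461611", "79461992"]

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_dmr_bed([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_round_trip_identity(self, tmp_path):
        dmrs = [
            self._dmr(),
            self._dmr(chrom="chr2", start=100, end=300, mark="5hmC",
                      mean_diff=0.15789473684210525, significant=False),
        ]
        path = tmp_path / "rt.bed"
        write_dmr_bed(dmrs, path)
        back = read_dmr_bed(path)
        ordered = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end, d.mark))
        assert back == ordered

    def test_unsorted_input_sorted_on_write(self, tmp_path):
        dmrs = [self._dmr(start=500, end=600), self._dmr(start=100, end=200)]
        path = tmp_path / "sorted.bed"
        write_dmr_bed(dmrs, path)
        starts = [int(l.split("\t")[1]) for l in path.read_text().splitlines()[1:]]
        assert starts == sorted(starts)


def test_parse_region_string_en_dash():
    assert parse_region_string("chr1:1,001–2,000") == ("chr1", 1000, 2000)
    with pytest.raises(ValueError):
        parse_region_string("chr1:500-499")


def test_region_matrix_round_trip(tmp_path):
    matrix = pd.DataFrame(
        np.arange(6, dtype=float).reshape(2, 3),
        index=pd.Index(["chr1:0-10", "chr1:20-30"], name="region"),
        columns=["s01", "s02", "s03"],
    )
    path = tmp_path / "matrix.tsv"
    write_region_matrix(matrix, path)
    pd.testing.assert_frame_equal(read_region_matrix(path), matrix)
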