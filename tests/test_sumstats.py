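"""Summary-statistic parsing, QC filters, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from twaskit.exceptions import ConfigError, EmptyResultError, ValidationError
from twaskit.sumstats import (
    SumStats,
    harmonize_alleles,
    load_sumstats,
    qc_sumstats,
    save_sumstats,
)


def _write(tmp_path, df, name="ss.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


def _frame(**overrides):
    base = {
        "SNP": ["rs1", "rs2", "rs3"],
        "CHR": ["1", "1", "1"],
        "BP": [100, 200, 300],
        "A1": ["A", "C", "G"],
        "A2": ["G", "T", "A"],
        "Z": [1.5, -0.7, 2.2],
        "MAF": [0.2, 0.3, 0.1],
        "N": [1000, 1000, 1000],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestLoad:
    def test_parses_wellformed_rows(self, sumstats_file):
        ss = load_sumstats(sumstats_file)
        assert len(ss) == 3
        assert list(ss.table.columns) == ["snp", "chrom", "pos", "a1", "a2", "z", "maf", "n"]
        assert ss.table["pos"].is_monotonic_increasing

    def test_beta_se_converted_to_z(self, tmp_path):
        df = _frame().drop(columns="Z")
        df["BETA"] = [0.1, 0.1, 0.1]
        df["SE"] = [0.05, 0.1, 0.2]
        ss = load_sumstats(_write(tmp_path, df))
        assert ss.table.set_index("snp").loc["rs1", "z"] == pytest.approx(2.0)

    def test_duplicate_rsid_names_offender(self, tmp_path):
        df = _frame(SNP=["rs1", "rs2", "rs2"])
        with pytest.raises(ValidationError, match="rs2"):
            load_sumstats(_write(tmp_path, df))

    def test_missing_required_column_is_config_error(self, tmp_path):
        df = _frame().drop(columns="MAF")
        with pytest.raises(ConfigError, match="MAF"):
            load_sumstats(_write(tmp_path, df))

    def test_column_map_renames(self, tmp_path):
        df = _frame().rename(columns={"SNP": "rsid", "Z": "zscore"})
        ss = load_sumstats(_write(tmp_path, df), column_map={"snp": "rsid", "z": "zscore"})
        assert len(ss) == 3

    def test_frequency_column_folded_to_maf(self, tmp_path):
        df = _frame(MAF=[0.8, 0.3, 0.95])
        ss = load_sumstats(_write(tmp_path, df))
        assert ss.table["maf"].max() <= 0.5
        assert ss.table.set_index("snp").loc["rs1", "maf"] == pytest.approx(0.2)

    def test_malformed_rows_dropped_and_logged(self, tmp_path):
        df = _frame(Z=["1.5", "not_a_number", "2.2"])
        ss = load_sumstats(_write(tmp_path, df))
        assert len(ss) == 2
        assert dict(ss.log)["malformed_rows"] == 1

    def test_roundtrip_preserves_values(self, tmp_path, sumstats_file):
        ss = load_sumstats(sumstats_file)
        out = tmp_path / "out.tsv"
        save_sumstats(ss, out)
        again = load_sumstats(out)
        pd.testing.assert_frame_equal(ss.table, again.table)


class TestQC:
    def _six_records(self):
        # one low-MAF, one A/T ambiguous, one C/G ambiguous, one bad id, two clean
        return SumStats(
            pd.DataFrame(
                {
                    "snp": ["rs10", "rs11", "rs12", "chr1:123", "rs14", "rs15"],
                    "chrom": "1",
                    "pos": [10, 20, 30, 40, 50, 60],
                    "a1": ["A", "A", "C", "A", "A", "C"],
                    "a2": ["G", "T", "G", "G", "G", "T"],
                    "z": 1.0,
                    "maf": [0.005, 0.2, 0.2, 0.2, 0.2, 0.2],
                    "n": 1000.0,
                }
            )
        )

    def test_rule_enumeration_on_fixture(self):
        out = qc_sumstats(self._six_records())
        assert sorted(out.table["snp"]) == ["rs14", "rs15"]
        removed = {rule: n for rule, n in out.log}
        assert removed["maf_below_min"] == 1
        assert removed["strand_ambiguous"] == 2
        assert removed["invalid_rsid"] == 1

    def test_removal_counts_partition_input(self):
        ss = self._six_records()
        out = qc_sumstats(ss)
        assert len(out) + sum(n for _, n in out.log) == len(ss)

    def test_clean_input_is_identity(self, sumstats_file):
        ss = load_sumstats(sumstats_file)
        out = qc_sumstats(ss)
        pd.testing.assert_frame_equal(out.table, ss.table)

    def test_zero_floor_and_no_ambiguous_is_identity(self, sumstats_file):
        ss = load_sumstats(sumstats_file)
        out = qc_sumstats(ss, maf_min=0.0)
        pd.testing.assert_frame_equal(out.table, ss.table)

    def test_idempotent(self):
        once = qc_sumstats(self._six_records())
        twice = qc_sumstats(once)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_all_removed_raises_with_breakdown(self):
        ss = SumStats(
            pd.DataFrame(
                {
                    "snp": ["rs1", "rs2"],
                    "chrom": "1",
                    "pos": [1, 2],
                    "a1": ["A", "C"],
                    "a2": ["T", "G"],
                    "z": 1.0,
                    "maf": 0.2,
                    "n": 100.0,
                }
            )
        )
        with pytest.raises(EmptyResultError) as err:
            qc_sumstats(ss)
        assert err.value.breakdown["strand_ambiguous"] == 2


class TestHarmonize:
    def _ss(self):
        return SumStats(
            pd.DataFrame(
                {
                    "snp": ["rs1", "rs2", "rs3"],
                    "chrom": "1",
                    "pos": [100, 200, 300],
                    "a1": ["A", "C", "A"],
                    "a2": ["G", "T", "G"],
                    "z": [2.0, 1.0, -1.0],
                    "maf": 0.2,
                    "n": 100.0,
                }
            )
        )

    def test_swapped_alleles_flip_sign(self):
        out = harmonize_alleles(self._ss(), [("rs1", "G", "A")])
        assert out.table.loc[0, "z"] == pytest.approx(-2.0)
        assert (out.table.loc[0, "a1"], out.table.loc[0, "a2"]) == ("G", "A")

    def test_identical_coding_unchanged(self):
        out = harmonize_alleles(self._ss(), [("rs1", "A", "G")])
        assert out.table.loc[0, "z"] == pytest.approx(2.0)

    def test_strand_flip_resolved_by_complement(self):
        # reference codes rs2 on the other strand: C/T -> G/A
        out = harmonize_alleles(self._ss(), [("rs2", "G", "A")])
        assert out.table.loc[0, "z"] == pytest.approx(1.0)
        out2 = harmonize_alleles(self._ss(), [("rs2", "A", "G")])  # flipped + swapped
        assert out2.table.loc[0, "z"] == pytest.approx(-1.0)

    def test_mismatched_alleles_dropped_and_logged(self):
        out = harmonize_alleles(self._ss(), [("rs1", "A", "C"), ("rs2", "C", "T")])
        assert list(out.table["snp"]) == ["rs2"]
        assert dict(out.log)["allele_mismatch"] == 1

    def test_output_follows_reference_order(self):
        bim = [("rs3", "A", "G"), ("rs1", "A", "G")]
        out = harmonize_alleles(self._ss(), bim)
        assert list(out.table["snp"]) == ["rs3", "rs1"]

    def test_empty_intersection_raises(self):
        with pytest.raises(EmptyResultError):
            harmonize_alleles(self._ss(), [("rs99", "A", "G")])

    def test_idempotent_within_one_frame(self):
        bim = [("rs1", "G", "A"), ("rs2", "C", "T"), ("rs3", "A", "G")]
        once = harmonize_alleles(self._ss(), bim)
        twice = harmonize_alleles(once, bim)
        np.testing.assert_allclose(once.table["z"], twice.table["z"])
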