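"""Affinity-table parsing, label transforms, redundancy filter and splits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panbind.data import (
    BindingSample,
    Dataset,
    binarize_ic50,
    binarize_t_half,
    inverse_transform,
    log_transform_ic50,
    loao_folds,
    parse_affinity_table,
    redundancy_filter,
    train_val_split,
)
from panbind.errors import (
    DatasetSizeError,
    DomainError,
    EmptyDatasetError,
    FoldError,
    TableFormatError,
)

ALLELES = {
    "HLA-A*02:01": "A" * 372,
    "HLA-B*07:02": "C" * 372,
    "HLA-C*04:01": "D" * 372,
}


def _write_table(tmp_path, rows, header="allele\tpeptide\tmeasurement_type\tmeasurement_value"):
    p = tmp_path / "table.tsv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


class TestParseAffinityTable:
    def test_drops_and_counts(self, tmp_path):
        """5 rows with one short peptide and one unknown allele -> 3 samples."""
        path = _write_table(tmp_path, [
            "HLA-A*02:01\tHLNPNKTKR\tic50\t100",
            "HLA-A*02:01\tAAAAAAAAA\tic50\t900",
            "HLA-B*07:02\tHLNPNKTK\tic50\t50",      # length 8
            "HLA-X*99:99\tKLMNPQRST\tic50\t50",      # unknown allele
            "HLA-C*04:01\tKLMNPQRST\tic50\t2000",
        ])
        ds, report = parse_affinity_table(path, ALLELES)
        assert len(ds) == 3
        assert report.dropped_length == 1
        assert report.dropped_allele == 1
        assert report.kept == 3

    def test_header_only_is_empty(self, tmp_path):
        path = _write_table(tmp_path, [])
        with pytest.raises(EmptyDatasetError):
            parse_affinity_table(path, ALLELES)

    def test_missing_column(self, tmp_path):
        path = _write_table(tmp_path, ["HLA-A*02:01\tHLNPNKTKR\t100"],
                            header="allele\tpeptide\tmeasurement_value")
        with pytest.raises(TableFormatError):
            parse_affinity_table(path, ALLELES)

    def test_duplicate_rows_collapse(self, tmp_path):
        path = _write_table(tmp_path, [
            "HLA-A*02:01\tHLNPNKTKR\tic50\t100",
            "HLA-A*02:01\tHLNPNKTKR\tic50\t200",
        ])
        ds, report = parse_affinity_table(path, ALLELES)
        assert len(ds) == 1
        assert ds.samples[0].measurement_value == 100  # first wins
        assert report.dropped_duplicate == 1

    def test_qualified_values_use_bound(self, tmp_path):
        path = _write_table(tmp_path, ["HLA-A*02:01\tHLNPNKTKR\tic50\t>20000"])
        ds, _ = parse_affinity_table(path, ALLELES)
        assert ds.samples[0].measurement_value == 20000
        assert ds.samples[0].binary_label == 0

    def test_t_half_and_binary_types(self, tmp_path):
        path = _write_table(tmp_path, [
            "HLA-A*02:01\tHLNPNKTKR\tt1/2\t30",
            "HLA-A*02:01\tAAAAAAAAA\tbinary\t1",
        ])
        ds, _ = parse_affinity_table(path, ALLELES)
        by_type = {s.measurement_type: s for s in ds.samples}
        assert by_type["t_half"].binary_label == 1
        assert by_type["binary"].binary_label == 1

    def test_column_map_dialect(self, tmp_path):
        path = _write_table(
            tmp_path, ["HLA-A*02:01\tHLNPNKTKR\tic50\t100"],
            header="mhc\tsequence\tmeas_type\tmeas_value")
        ds, _ = parse_affinity_table(path, ALLELES, column_map={
            "allele": "mhc", "peptide": "sequence",
            "measurement_type": "meas_type", "measurement_value": "meas_value"})
        assert len(ds) == 1

    def test_parsed_samples_all_encode(self, tmp_path):
        from panbind.encoding import encode_peptide
        path = _write_table(tmp_path, [
            "HLA-A*02:01\tHLNPNKTKR\tic50\t100",
            "HLA-B*07:02\tWYVQFMRAC\tic50\t600",
        ])
        ds, _ = parse_affinity_table(path, ALLELES)
        for s in ds.samples:
            assert encode_peptide(s.peptide).shape == (1, 9, 20)


class TestLabelTransforms:
    def test_log_of_500_is_class_boundary(self):
        assert log_transform_ic50(500) == pytest.approx(6.2146, abs=1e-4)

    @pytest.mark.parametrize("x,expected", [(1, 0.0), (0, 0.0)])
    def test_log_small_values_clamped(self, x, expected):
        assert log_transform_ic50(x) == expected

    def test_log_negative_rejected(self):
        with pytest.raises(DomainError):
            log_transform_ic50(-1)

    def test_inverse_of_boundary(self):
        assert inverse_transform(math.log(500)) == pytest.approx(500, abs=0.01)

    def test_inverse_of_zero(self):
        assert inverse_transform(0) == 1.0

    def test_inverse_clamps_to_range_top(self):
        assert inverse_transform(20) == 80000  # exp(20) ~ 4.85e8

    @given(st.floats(min_value=1, max_value=80000))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_above_1nM(self, x):
        assert inverse_transform(log_transform_ic50(x)) == pytest.approx(x, rel=1e-9)

    @pytest.mark.parametrize("ic50,label", [(500, 1), (80000, 0), (0.5, 1), (501, 0)])
    def test_binarize_ic50(self, ic50, label):
        assert binarize_ic50(ic50) == label

    @pytest.mark.parametrize("minutes,label", [(119, 1), (120, 0), (0, 1)])
    def test_binarize_t_half(self, minutes, label):
        assert binarize_t_half(minutes) == label

    @pytest.mark.parametrize("fn", [binarize_ic50, binarize_t_half])
    def test_binarize_negative_rejected(self, fn):
        with pytest.raises(DomainError):
            fn(-0.1)

    @given(st.floats(min_value=1, max_value=80000))
    @settings(max_examples=200, deadline=None)
    def test_binarize_consistent_in_log_domain(self, x):
        assert (binarize_ic50(x) == 1) == (log_transform_ic50(x) <= math.log(500))


def _dataset(peptide_counts: dict[str, int]) -> Dataset:
    samples = []
    alleles = list(ALLELES)
    for pep, count in peptide_counts.items():
        for i in range(count):
            samples.append(BindingSample.from_measurement(
                alleles[i % len(alleles)], pep, "ic50", 100.0 * (i + 1)))
    return Dataset(samples, dict(ALLELES))


class TestRedundancyFilter:
    def test_similar_peptides_cluster(self):
        """8/9 identity >= 0.7: the better-sampled peptide's cluster wins."""
        ds = _dataset({"AAAAAAAAA": 3, "AAAAAAAAR": 1})
        out = redundancy_filter(ds)
        assert {s.peptide for s in out.samples} == {"AAAAAAAAA"}
        assert len(out) == 3

    def test_dissimilar_peptides_kept(self):
        """6/9 identity < 0.7: both peptides found their own clusters."""
        ds = _dataset({"AAAAAAAAA": 1, "AAAAAARRR": 1})
        out = redundancy_filter(ds)
        assert {s.peptide for s in out.samples} == {"AAAAAAAAA", "AAAAAARRR"}

    def test_singleton_unchanged(self):
        ds = _dataset({"HLNPNKTKR": 1})
        assert len(redundancy_filter(ds)) == 1

    def test_idempotent(self):
        ds = _dataset({"AAAAAAAAA": 3, "AAAAAAAAR": 2, "AAAAAARRR": 1,
                       "WYVQFMRAC": 2, "WYVQFMRAA": 1})
        once = redundancy_filter(ds)
        twice = redundancy_filter(once)
        assert [s.peptide for s in twice.samples] == [s.peptide for s in once.samples]

    def test_never_grows_and_matches_bruteforce_threshold(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        peps = {"".join(rng.choice(list(aas), 9)): 1 for _ in range(30)}
        ds = _dataset(peps)
        out = redundancy_filter(ds)
        assert len(out) <= len(ds)
        kept = {s.peptide for s in out.samples}
        # surviving representatives are pairwise below the identity threshold
        kept = sorted(kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                ident = sum(x == y for x, y in zip(a, b))
                assert ident < math.ceil(9 * 0.7)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(DomainError):
            redundancy_filter(_dataset({"AAAAAAAAA": 1}), bad)


class TestSplits:
    def test_ratio_100(self):
        ds = _dataset({f"{aa}AAAAAAAA": 1 for aa in "ACDEFGHIKL"})
        ds.samples = ds.samples * 10  # 100 samples
        tr, va = train_val_split(ds, seed=0)
        assert (len(tr), len(va)) == (80, 20)

    def test_ratio_minimum(self):
        ds = _dataset({f"{aa}AAAAAAAA": 1 for aa in "ACDEF"})
        tr, va = train_val_split(ds, seed=0)
        assert (len(tr), len(va)) == (4, 1)

    def test_too_small(self):
        with pytest.raises(DatasetSizeError):
            train_val_split(_dataset({"AAAAAAAAA": 4}), seed=0)

    def test_deterministic_and_partition(self):
        ds = _dataset({f"{aa}{bb}AAAAAAA": 1 for aa in "ACDEFG" for bb in "KLMNP"})
        tr1, va1 = train_val_split(ds, seed=7)
        tr2, va2 = train_val_split(ds, seed=7)
        key = lambda d: sorted((s.allele, s.peptide) for s in d.samples)
        assert key(tr1) == key(tr2) and key(va1) == key(va2)
        assert len(tr1) + len(va1) == len(ds)
        assert not set(key(tr1)) & set(key(va1))

    def test_loao_folds(self):
        ds = _dataset({f"{aa}AAAAAAAA": 3 for aa in "ACDEF"})
        folds = loao_folds(ds)
        assert len(folds) == 3  # one per allele
        for allele, tr, te in folds:
            assert len(tr) + len(te) == len(ds)
            assert all(s.allele == allele for s in te.samples)
            assert all(s.allele != allele for s in tr.samples)

    def test_loao_single_allele(self):
        ds = _dataset({"AAAAAAAAA": 1})
        with pytest.raises(FoldError):
            loao_folds(ds)
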