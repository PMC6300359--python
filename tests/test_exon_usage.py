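"""Unit and property tests for PSI computation and exon-usage testing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titinmech import exon_usage, simulate
from titinmech.errors import InvalidInputError
from titinmech.exon_usage import (
    ExonRecord,
    SampleCounts,
    adjust_exon_counts,
    compute_psi,
    differential_exon_usage,
    neg_log10_p,
    normalize_counts,
    pevk_residue_count,
    psi_profile,
)

from conftest import make_samples


@pytest.mark.parametrize(
    "ir, er, length, read_len, expected",
    [
        (100, 50, 100, 100, (100 / 199, 50 / 99)),
        (0, 0, 100, 100, (0.0, 0.0)),
        (199, 0, 100, 100, (1.0, 0.0)),
    ],
)
def test_normalize_counts_examples(ir, er, length, read_len, expected):
    ir_n, er_n = normalize_counts(ir, er, length, read_len)
    assert ir_n == pytest.approx(expected[0])
    assert er_n == pytest.approx(expected[1])


def test_normalize_counts_rejects_bad_lengths():
    with pytest.raises(InvalidInputError):
        normalize_counts(1, 1, 0, 100)
    with pytest.raises(InvalidInputError):
        normalize_counts(1, 1, 100, 1)


@pytest.mark.parametrize(
    "ir_n, er_n, expected",
    [(0.5, 0.0, 100.0), (0.0, 0.5, 0.0), (100 / 199, 50 / 99, 49.87)],
)
def test_compute_psi_examples(ir_n, er_n, expected):
    assert compute_psi(ir_n, er_n) == pytest.approx(expected, abs=5e-3)


def test_compute_psi_zero_coverage_is_nan_not_error():
    assert math.isnan(compute_psi(0.0, 0.0))


@given(
    ir=st.integers(1, 10_000),
    er=st.integers(0, 10_000),
    scale=st.floats(0.01, 100.0),
)
@settings(max_examples=100, deadline=None)
def test_psi_scale_invariance(ir, er, scale):
    """Multiplying IR and ER by one constant leaves PSI unchanged."""
    ir_n, er_n = normalize_counts(ir, er, 120, 100)
    ir_s, er_s = normalize_counts(ir * scale, er * scale, 120, 100)
    assert compute_psi(ir_s, er_s) == pytest.approx(compute_psi(ir_n, er_n))


@pytest.mark.parametrize(
    "e, g, gbar, expected",
    [(10, 100, 200, 20), (10, 150, 150, 10), (7, 140, 100, 5)],
)
def test_adjust_exon_counts_examples(e, g, gbar, expected):
    assert adjust_exon_counts(e, g, gbar) == pytest.approx(expected)


def test_adjust_exon_counts_rejects_nonpositive_gene_count():
    with pytest.raises(InvalidInputError):
        adjust_exon_counts(10, 0, 100)


def test_adjustment_preserves_exon_ratios():
    e = np.array([5.0, 20.0, 35.0])
    adjusted = np.array([adjust_exon_counts(v, 80.0, 120.0) for v in e])
    assert adjusted[1] / adjusted[0] == pytest.approx(e[1] / e[0])
    assert adjusted[2] / adjusted[1] == pytest.approx(e[2] / e[1])


def _two_exon_annotation():
    return [
        ExonRecord(1, "PEVK", 300, 100),
        ExonRecord(2, "PEVK", 150, 50),
    ]


def _sample(ir, er, sample_id="s", genotype="WT", read_length=100):
    counts = pd.DataFrame(
        {"exon_index": [1, 2], "inclusion_reads": ir, "exclusion_reads": er}
    )
    return SampleCounts(sample_id, genotype, "diaphragm", read_length, counts)


def test_psi_profile_flags_zero_coverage():
    sample = _sample([100, 0], [50, 0])
    prof = psi_profile(sample, _two_exon_annotation())
    assert not math.isnan(prof.psi.iloc[0])
    assert math.isnan(prof.psi.iloc[1])


def test_pevk_residue_count_examples():
    ann = _two_exon_annotation()
    assert pevk_residue_count({1: 100.0, 2: 50.0}, ann) == pytest.approx(125.0)
    assert pevk_residue_count({1: 0.0, 2: 0.0}, ann) == pytest.approx(0.0)


def test_pevk_residue_count_names_missing_exon():
    ann = _two_exon_annotation()
    with pytest.raises(InvalidInputError, match="exon 2"):
        pevk_residue_count({1: 100.0}, ann)
    with pytest.raises(InvalidInputError, match="exon 1"):
        pevk_residue_count({1: math.nan, 2: 50.0}, ann)


@pytest.mark.parametrize("method", ["pooled", "permutation"])
def test_differential_identical_groups_gives_zero_delta(method):
    ann = _two_exon_annotation()
    a = [_sample([100, 50], [50, 50], f"a{i}") for i in range(3)]
    b = [_sample([100, 50], [50, 50], f"b{i}") for i in range(3)]
    res = differential_exon_usage(a, b, ann, method=method)
    assert np.allclose(res.delta_psi, 0.0)


def test_differential_complete_separation_small_p():
    """Fully included vs fully skipped exon at depth >= 1000, 4v4 samples."""
    ann = _two_exon_annotation()
    a = [_sample([2000, 1000], [0, 0], f"a{i}") for i in range(4)]
    b = [_sample([0, 1000], [1000, 0], f"b{i}") for i in range(4)]
    res = differential_exon_usage(a, b, ann)
    row = res[res.exon_index == 1].iloc[0]
    assert row.delta_psi == pytest.approx(100.0)
    assert row.p_value < 0.01


def test_differential_all_zero_group_flags_missing_p():
    ann = _two_exon_annotation()
    a = [_sample([100, 0], [50, 0], f"a{i}") for i in range(2)]
    b = [_sample([100, 10], [50, 10], f"b{i}") for i in range(2)]
    res = differential_exon_usage(a, b, ann)
    assert math.isnan(res[res.exon_index == 2].p_value.iloc[0])


def test_permutation_test_exact_minimum_at_small_n():
    """4v4 exact enumeration: complete separation gives p = 2/70."""
    ann = _two_exon_annotation()
    a = [_sample([2000, 1000], [0, 0], f"a{i}") for i in range(4)]
    b = [_sample([0, 1000], [1000, 0], f"b{i}") for i in range(4)]
    res = differential_exon_usage(a, b, ann, method="permutation")
    assert res[res.exon_index == 1].p_value.iloc[0] == pytest.approx(2 / 70)


def test_deleted_exons_delta_psi_minus_100(titin_annotation, wt_probs, mutant_probs):
    """Simulated genotype comparison recovers -100 points for deleted exons."""
    wt = make_samples(wt_probs, titin_annotation, 4, 2000, "WT", 0)
    mut = make_samples(mutant_probs, titin_annotation, 4, 2000, "Delta112-158", 100)
    res = differential_exon_usage(mut, wt, titin_annotation)
    fully_deleted = res[(res.exon_index >= 112) & (res.exon_index <= 143)]
    assert np.allclose(fully_deleted.delta_psi, -100.0)
    assert (fully_deleted.p_value < 0.01).all()


def test_neg_log10_p_capped_at_six():
    out = neg_log10_p([1.0, 1e-3, 1e-12, np.nan])
    assert out[0] == pytest.approx(0.0)
    assert out[1] == pytest.approx(3.0)
    assert out[2] == pytest.approx(6.0)
    assert math.isnan(out[3])


def test_group_psi_pooled_vs_per_sample():
    ann = _two_exon_annotation()
    # per-sample PSI mean differs from pooled PSI when depths differ
    a = [_sample([100, 50], [100, 50], "a0"), _sample([3000, 50], [1000, 50], "a1")]
    per_sample = exon_usage.group_psi(a, ann)
    pooled = exon_usage.group_psi(a, ann, pooled=True)
    assert per_sample.psi.iloc[0] != pytest.approx(pooled.psi.iloc[0])
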