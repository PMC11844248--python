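import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commflux.errors import ValidationError
from commflux.expression import (
    CountMatrix,
    GrowthCurve,
    SizeFactors,
    absolute_abundance,
    growth_rate_from_od,
    log_normalize,
    nfpk,
    read_counts_tsv,
    read_od_tsv,
    size_factors,
    split_counts_by_member,
    write_counts_tsv,
    write_od_tsv,
)
from commflux.synthetic_data import simulate_counts, simulate_od

from oracles import median_of_ratios


def cm_from_array(arr, members=None, lengths=None, samples=None):
    arr = np.asarray(arr)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(
        counts=pd.DataFrame(arr, index=genes, columns=samples),
        gene_lengths={g: (lengths or {}).get(g, 1000.0) for g in genes},
        gene_member={g: (members or {}).get(g, "m1") for g in genes},
    )


class TestCountMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            cm_from_array([[-1, 2]])

    def test_missing_length_rejected(self):
        with pytest.raises(ValidationError):
            CountMatrix(
                counts=pd.DataFrame([[1]], index=["g0"], columns=["s0"]),
                gene_lengths={},
                gene_member={"g0": "m"},
            )

    def test_missing_member_rejected(self):
        with pytest.raises(ValidationError):
            CountMatrix(
                counts=pd.DataFrame([[1]], index=["g0"], columns=["s0"]),
                gene_lengths={"g0": 100.0},
                gene_member={},
            )


class TestSplit:
    def test_two_member_partition(self):
        cm = cm_from_array(
            [[1, 2], [3, 4], [5, 6], [7, 8]],
            members={"g0": "a", "g1": "a", "g2": "b", "g3": "b"},
        )
        parts = split_counts_by_member(cm)
        assert sorted(parts) == ["a", "b"]
        assert parts["a"].genes == ["g0", "g1"]
        assert parts["b"].genes == ["g2", "g3"]
        # concatenating back reproduces the input
        rebuilt = pd.concat([parts["a"].counts, parts["b"].counts])
        pd.testing.assert_frame_equal(rebuilt.sort_index(), cm.counts.sort_index())

    def test_single_member_identity(self):
        cm = cm_from_array([[1, 2], [3, 4]])
        parts = split_counts_by_member(cm)
        assert list(parts) == ["m1"]
        pd.testing.assert_frame_equal(parts["m1"].counts, cm.counts)

    def test_generator_manifest_counts(self, benchmark):
        parts = split_counts_by_member(benchmark.counts)
        expected = {}
        for g, m in benchmark.counts.gene_member.items():
            expected[m] = expected.get(m, 0) + 1
        assert {m: len(p.genes) for m, p in parts.items()} == expected


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        cm = cm_from_array([[10, 20], [100, 200]])
        sf = size_factors(cm)
        assert sf["s0"] == pytest.approx(0.7071, abs=1e-4)
        assert sf["s1"] == pytest.approx(1.4142, abs=1e-4)

    def test_single_sample_is_one(self):
        cm = cm_from_array([[10], [100]])
        assert size_factors(cm)["s0"] == pytest.approx(1.0)

    def test_column_scaling_equivariance(self):
        # Size factors are defined up to a common scale, so scaling one
        # column by 2 doubles that column's factor relative to the others.
        base = np.array([[10, 20], [100, 200], [7, 9]])
        doubled = base.copy()
        doubled[:, 1] *= 2
        sf1 = size_factors(cm_from_array(base))
        sf2 = size_factors(cm_from_array(doubled))
        ratio_before = sf1["s1"] / sf1["s0"]
        ratio_after = sf2["s1"] / sf2["s0"]
        assert ratio_after == pytest.approx(2.0 * ratio_before, rel=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 500, size=(40, 5))
        counts[:5] += 1  # ensure some all-positive genes
        ours = size_factors(cm_from_array(counts))
        oracle = median_of_ratios(counts)
        for j, s in enumerate(oracle):
            assert ours[f"s{j}"] == pytest.approx(s, rel=1e-12)

    def test_all_zero_gene_matrix_rejected(self):
        with pytest.raises(ValidationError):
            size_factors(cm_from_array([[0, 1], [1, 0]]))

    def test_nb_recovery_within_five_percent(self):
        true_sf = {"s0": 1.0, "s1": 2.0}
        cm = simulate_counts(
            base_means={f"g{i}": 200.0 for i in range(500)},
            sample_size_factors=true_sf,
            sample_condition={"s0": "c", "s1": "c"},
            fold_changes={},
            dispersion=0.05,
            seed=11,
            gene_lengths={f"g{i}": 1000.0 for i in range(500)},
            gene_member={f"g{i}": "m" for i in range(500)},
        )
        sf = size_factors(cm)
        ratio = sf["s1"] / sf["s0"]
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestNfpk:
    def test_worked_example(self):
        cm = cm_from_array([[100]], lengths={"g0": 500.0})
        sf = SizeFactors({"s0": 2.0})
        assert nfpk(cm, sf).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count_is_zero(self):
        cm = cm_from_array([[0]])
        assert nfpk(cm, SizeFactors({"s0": 3.0})).iloc[0, 0] == 0.0

    def test_identity_scaling(self):
        cm = cm_from_array([[42]], lengths={"g0": 1000.0})
        assert nfpk(cm, SizeFactors({"s0": 1.0})).iloc[0, 0] == pytest.approx(42.0)

    def test_invariant_to_joint_scaling(self):
        cm1 = cm_from_array([[30, 60]])
        cm2 = cm_from_array([[90, 60]])
        t1 = nfpk(cm1, SizeFactors({"s0": 1.0, "s1": 2.0}))
        t2 = nfpk(cm2, SizeFactors({"s0": 3.0, "s1": 2.0}))
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_sample_factor_rejected(self):
        with pytest.raises(ValidationError):
            nfpk(cm_from_array([[1, 2]]), SizeFactors({"s0": 1.0}))


class TestLogNormalize:
    def test_zero_count_maps_to_zero(self):
        cm = cm_from_array([[0]])
        assert log_normalize(cm, SizeFactors({"s0": 1.0})).iloc[0, 0] == 0.0

    def test_three_maps_to_two(self):
        cm = cm_from_array([[3]])
        assert log_normalize(cm, SizeFactors({"s0": 1.0})).iloc[0, 0] == pytest.approx(2.0)

    def test_invariance_under_size_factor_scaling(self):
        t1 = log_normalize(cm_from_array([[8, 5]]), SizeFactors({"s0": 2.0, "s1": 1.0}))
        t2 = log_normalize(cm_from_array([[16, 5]]), SizeFactors({"s0": 4.0, "s1": 1.0}))
        pd.testing.assert_frame_equal(t1, t2)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            log_normalize(cm_from_array([[1]]), SizeFactors({"s0": 1.0}), pseudocount=0.0)


class TestGrowthRate:
    def test_two_point_closed_form(self):
        curve = GrowthCurve(times=[0.0, 48.0], od=[0.05, 0.20])
        fit = growth_rate_from_od(curve)
        assert fit.rate == pytest.approx(math.log(4) / 48.0, abs=1e-12)

    def test_constant_od_is_zero(self):
        curve = GrowthCurve(times=[0.0, 10.0, 20.0], od=[0.3, 0.3, 0.3])
        assert growth_rate_from_od(curve).rate == 0.0

    def test_noiseless_exponential_exact(self):
        curve = simulate_od(0.1, od0=0.05, times=np.linspace(0, 30, 10))
        fit = growth_rate_from_od(curve)
        assert fit.rate == pytest.approx(0.1, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_window_too_small_rejected(self):
        curve = GrowthCurve(times=[0.0, 10.0, 20.0], od=[0.1, 0.2, 0.4])
        with pytest.raises(ValidationError):
            growth_rate_from_od(curve, window=(4.0, 6.0))

    def test_explicit_window_restricts_fit(self):
        # exponential at 0.1/h up to t=20, then flat
        t = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0])
        od = np.where(t <= 20, 0.05 * np.exp(0.1 * t), 0.05 * np.exp(2.0))
        fit = growth_rate_from_od(GrowthCurve(times=t, od=od), window=(0.0, 20.0))
        assert fit.rate == pytest.approx(0.1, abs=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_time_rescaling_equivariance(self, scale):
        t = np.linspace(0.0, 20.0, 6)
        od = 0.07 * np.exp(0.15 * t)
        base = growth_rate_from_od(GrowthCurve(times=t, od=od)).rate
        rescaled = growth_rate_from_od(GrowthCurve(times=t * scale, od=od)).rate
        assert rescaled * scale == pytest.approx(base, rel=1e-9)


class TestAbsoluteAbundance:
    def test_worked_example(self):
        out = absolute_abundance(2.0, {"A": 0.8, "B": 0.2})
        assert out == {"A": pytest.approx(1.6), "B": pytest.approx(0.4)}

    def test_zero_od(self):
        assert absolute_abundance(0.0, {"A": 0.5}) == {"A": 0.0}

    def test_sum_preserved(self):
        fr = {"A": 0.4, "B": 0.35, "C": 0.1}
        out = absolute_abundance(3.0, fr)
        assert sum(out.values()) == pytest.approx(3.0 * sum(fr.values()))

    def test_oversum_rejected(self):
        with pytest.raises(ValidationError):
            absolute_abundance(1.0, {"A": 0.7, "B": 0.5})


class TestTsvRoundTrips:
    def test_counts_roundtrip(self, tmp_path):
        cm = cm_from_array([[1, 2], [3, 4]], members={"g0": "a", "g1": "b"})
        write_counts_tsv(cm, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        assert back.gene_member == cm.gene_member

    def test_od_roundtrip(self, tmp_path):
        curves = [
            simulate_od(0.1, 0.05, [0.0, 12.0, 24.0], reactor="r1", condition="x"),
            simulate_od(0.2, 0.05, [0.0, 12.0, 24.0], reactor="r2", condition="y"),
        ]
        write_od_tsv(curves, tmp_path / "od.tsv")
        back = read_od_tsv(tmp_path / "od.tsv")
        assert len(back) == 2
        np.testing.assert_allclose(back[0].od, curves[0].od)
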