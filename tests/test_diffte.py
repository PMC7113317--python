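"""Normalization, expression filtering, TE and the differential-TE test."""

import numpy as np
import pandas as pd
import pytest

from ribobuffer import synthdata as sd
from ribobuffer.diffte import (
    DiffTEConfig,
    NormalizationConfig,
    compute_te,
    differential_te,
    filter_expressed,
    normalize,
    partition_te_sets,
)


def _meta(samples, condition_of):
    return pd.DataFrame(
        [(s, condition_of(s), "rna", i + 1) for i, s in enumerate(samples)],
        columns=["sample", "condition", "layer", "replicate"],
    )


class TestNormalize:
    def test_cpm_arithmetic_and_column_sums(self):
        counts = pd.DataFrame({"s1": [1, 1, 2], "s2": [10, 20, 70]}, index=list("abc"))
        cpm = normalize(counts)
        assert list(cpm["s1"]) == [250_000, 250_000, 500_000]
        assert cpm.sum().values == pytest.approx([1e6, 1e6])

    def test_identical_samples_equal_size_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20]}, index=list("abc"))
        out = normalize(counts, NormalizationConfig(method="median_of_ratios"))
        pd.testing.assert_series_equal(out["s1"], out["s2"], check_names=False)

    def test_median_of_ratios_undoes_depth_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50).astype(float)
        counts = pd.DataFrame({"s1": base, "s2": 3 * base})
        out = normalize(counts, NormalizationConfig(method="median_of_ratios"))
        np.testing.assert_allclose(out["s1"], out["s2"])

    def test_all_zero_column_raises_with_name(self):
        counts = pd.DataFrame({"ok": [1, 2], "dead": [0, 0]})
        with pytest.raises(ValueError, match="dead"):
            normalize(counts)


class TestFilterExpressed:
    def _frames(self, rna_rows, rfp_rows):
        genes = [f"g{i}" for i in range(len(rna_rows))]
        rna = pd.DataFrame(rna_rows, index=genes, columns=["a1", "a2"])
        rfp = pd.DataFrame(rfp_rows, index=genes, columns=["b1", "b2"])
        meta_rna = _meta(["a1", "a2"], lambda s: "X")
        meta_rfp = _meta(["b1", "b2"], lambda s: "X")
        # second condition has no samples of its own in this minimal setup:
        # duplicate condition X as both sides of the pair
        return rna, rfp, meta_rna, meta_rfp

    def test_thresholds_are_strict(self):
        rna, rfp, m1, m2 = self._frames(
            [[60, 55], [60, 55], [50, 60]], [[30, 26], [30, 20], [30, 26]]
        )
        kept = filter_expressed(rna, rfp, m1, m2, "X", "X")
        # g0 passes; g1 fails RFP (20 <= 25); g2 fails RNA (50 is not > 50)
        assert kept == {"g0"}

    def test_pass_if_all_reps_clear_in_one_condition(self):
        genes = ["g0"]
        rna = pd.DataFrame([[60, 55, 10, 10]], index=genes, columns=["a1", "a2", "b1", "b2"])
        rfp = pd.DataFrame([[30, 26, 1, 1]], index=genes, columns=["c1", "c2", "d1", "d2"])
        meta_rna = _meta(["a1", "a2", "b1", "b2"], lambda s: "A" if s.startswith("a") else "B")
        meta_rfp = _meta(["c1", "c2", "d1", "d2"], lambda s: "A" if s.startswith("c") else "B")
        assert filter_expressed(rna, rfp, meta_rna, meta_rfp, "A", "B") == {"g0"}

    def test_mismatched_gene_sets_raise(self):
        rna = pd.DataFrame([[60, 60]], index=["g0"], columns=["a1", "a2"])
        rfp = pd.DataFrame([[30, 30]], index=["other"], columns=["a1", "a2"])
        m = _meta(["a1", "a2"], lambda s: "X")
        with pytest.raises(ValueError, match="mismatched"):
            filter_expressed(rna, rfp, m, m, "X", "X")


class TestComputeTE:
    def _pair(self, rfp_val, rna_val):
        rna = pd.DataFrame({"rna_s": [rna_val]}, index=["g"])
        rfp = pd.DataFrame({"rfp_s": [rfp_val]}, index=["g"])
        meta_rna = pd.DataFrame(
            [("rna_s", "X", "rna", 1)], columns=["sample", "condition", "layer", "replicate"]
        )
        meta_rfp = pd.DataFrame(
            [("rfp_s", "X", "rfp", 1)], columns=["sample", "condition", "layer", "replicate"]
        )
        return rfp, rna, meta_rfp, meta_rna

    @pytest.mark.parametrize(
        "rfp,rna,c,expected",
        [(20, 10, 1e-12, 2.0), (7, 7, 0.5, 1.0), (0, 10, 0.5, 0.5 / 10.5)],
    )
    def test_ratio_formula(self, rfp, rna, c, expected):
        f, r, mf, mr = self._pair(rfp, rna)
        te = compute_te(f, r, mf, mr, pseudocount=c)
        assert te.iloc[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_unpaired_samples_raise(self):
        f, r, mf, mr = self._pair(1, 1)
        mf_bad = mf.assign(replicate=[2])
        with pytest.raises(ValueError, match="unpaired"):
            compute_te(f, r, mf_bad, mr)


@pytest.fixture(scope="module")
def two_condition_cohort():
    specs = sd.generate_gene_specs(400, seed=21)
    sim = sd.SimulationConfig(n_genes=400, seed=21)
    design = sd.ExperimentDesign(conditions=("2iL", "SL"))
    rna, rfp = sd.simulate_counts(specs, design, sim)
    return specs, rna, rfp


class TestDifferentialTE:
    def test_identical_conditions_give_null_stats(self):
        counts = pd.DataFrame(
            {
                "a1": [1000, 500, 800] * 20,
                "a2": [900, 550, 780] * 20,
                "b1": [1000, 500, 800] * 20,
                "b2": [900, 550, 780] * 20,
            },
            index=[f"g{i}" for i in range(60)],
        )
        meta = _meta(list(counts.columns), lambda s: "A" if s.startswith("a") else "B")
        cm = sd.CountMatrix(counts, meta)
        res = differential_te(cm, cm, "A", "B")
        # RFP == RNA and cond_a == cond_b replicate-wise: exact zero deltas
        assert res["delta_te"].abs().max() == 0
        assert (res["p"] == 1).all()
        assert not res["called"].any()

    def test_antisymmetry_under_condition_swap(self, two_condition_cohort):
        _, rna, rfp = two_condition_cohort
        fwd = differential_te(rna, rfp, "2iL", "SL")
        rev = differential_te(rna, rfp, "SL", "2iL")
        np.testing.assert_allclose(fwd["delta_te"], -rev["delta_te"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_cpm_delta_te_scale_invariant(self, two_condition_cohort):
        _, rna, rfp = two_condition_cohort
        scaled = sd.CountMatrix(rna.counts.copy(), rna.meta)
        col = scaled.counts.columns[0]
        scaled.counts[col] = scaled.counts[col] * 4
        a = differential_te(rna, rfp, "2iL", "SL")
        b = differential_te(scaled, rfp, "2iL", "SL")
        common = a.index.intersection(b.index)
        # pseudocount effects only: tiny at the fixture's CPM scale
        np.testing.assert_allclose(
            a.loc[common, "delta_te"], b.loc[common, "delta_te"], atol=1e-3
        )

    def test_planted_te_shift_detected(self, two_condition_cohort):
        specs, rna, rfp = two_condition_cohort
        res = differential_te(rna, rfp, "2iL", "SL")
        planted = [
            s.gene_id
            for s in specs
            if s.mode in ("translational", "buffered") and s.gene_id in res.index
        ]
        sub = res.loc[planted]
        assert sub["called"].mean() > 0.9
        # recovered delta close to the planted magnitude
        truth = {s.gene_id: s.te_shift for s in specs}
        err = sub["delta_te"] - pd.Series(truth).loc[planted]
        assert err.abs().median() < 0.5

    def test_missing_condition_raises(self, two_condition_cohort):
        _, rna, rfp = two_condition_cohort
        with pytest.raises(ValueError, match="EPI"):
            differential_te(rna, rfp, "2iL", "EPI")

    def test_single_replicate_raises(self, two_condition_cohort):
        _, rna, rfp = two_condition_cohort
        crippled = sd.CountMatrix(
            rna.counts.drop(columns=["SL_rna_rep2"]),
            rna.meta[rna.meta["sample"] != "SL_rna_rep2"],
        )
        with pytest.raises(ValueError, match="replicate"):
            differential_te(crippled, rfp, "2iL", "SL")


class TestPartitionTESets:
    def _results(self, genes, called, direction="higher_in_ref"):
        return pd.DataFrame(
            {
                "called": [g in called for g in genes],
                "direction": [direction] * len(genes),
            },
            index=pd.Index(genes, name="gene_id"),
        )

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(10):
            called_a = set(rng.choice(genes, size=15, replace=False))
            called_b = set(rng.choice(genes, size=12, replace=False))
            sets = partition_te_sets(
                self._results(genes, called_a), self._results(genes, called_b)
            )
            assert sets["SL_only"] == called_a - called_b
            assert sets["EPI_only"] == called_b - called_a
            assert sets["common"] == called_a & called_b

    def test_uncalled_genes_absent_everywhere(self):
        genes = ["g0", "g1", "g2"]
        sets = partition_te_sets(
            self._results(genes, {"g0"}), self._results(genes, {"g0", "g1"})
        )
        for key in ("SL_only", "EPI_only", "common"):
            assert "g2" not in sets[key]
        assert sets["common"] == {"g0"} and sets["EPI_only"] == {"g1"}
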