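"""The synthetic generator: planted composition, count model, censoring,
transcript structure and footprint geometry."""

import numpy as np
import pytest

from ribobuffer import synthdata as sd


class TestGenerateGeneSpecs:
    def test_degenerate_fractions_all_null(self):
        specs = sd.generate_gene_specs(100, {"null": 1.0}, seed=0)
        assert len(specs) == 100
        assert all(
            s.mode == "null"
            and s.rna_shift == s.te_shift == s.protein_shift == 0
            for s in specs
        )

    def test_largest_remainder_exact_counts(self):
        specs = sd.generate_gene_specs(1000, {"buffered": 0.2, "null": 0.8}, seed=1)
        assert sum(s.mode == "buffered" for s in specs) == 200

    def test_default_fractions_apportion_exactly(self):
        specs = sd.generate_gene_specs(2000, seed=5)
        counts = {m: sum(s.mode == m for s in specs) for m in sd.MODES}
        assert counts == {
            m: round(2000 * f) for m, f in sd.DEFAULT_MODE_FRACTIONS.items()
        }

    def test_deterministic_for_seed(self):
        a = sd.generate_gene_specs(300, seed=9)
        b = sd.generate_gene_specs(300, seed=9)
        assert a == b
        c = sd.generate_gene_specs(300, seed=10)
        assert a != c

    def test_mode_invariants_hold(self):
        for s in sd.generate_gene_specs(500, seed=2):
            if s.mode == "buffered":
                assert s.te_shift == -s.rna_shift and s.protein_shift == 0
            elif s.mode == "transcriptional":
                assert s.te_shift == 0 and s.protein_shift == s.rna_shift
            elif s.mode == "translational":
                assert s.rna_shift == 0 and s.protein_shift == s.te_shift
            elif s.mode == "post_translational":
                assert s.rna_shift == s.te_shift == 0 and s.protein_shift != 0
            else:
                assert s.rna_shift == s.te_shift == s.protein_shift == 0

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError):
            sd.generate_gene_specs(10, {"null": 0.7})
        with pytest.raises(ValueError):
            sd.generate_gene_specs(10, {"exotic": 1.0})


class TestSimulateCounts:
    def _small(self, n=200, seed=0, **kw):
        specs = sd.generate_gene_specs(n, seed=seed)
        sim = sd.SimulationConfig(n_genes=n, seed=seed, **kw)
        design = sd.ExperimentDesign(conditions=("2iL", "SL"))
        return specs, design, sim

    def test_zero_depth_gives_zero_counts(self):
        specs, _, sim = self._small()
        design = sd.ExperimentDesign(
            conditions=("2iL", "SL"), library_depths={"SL_rna_rep1": 0}
        )
        rna, _ = sd.simulate_counts(specs, design, sim)
        assert (rna.counts["SL_rna_rep1"] == 0).all()
        assert (rna.counts.drop(columns="SL_rna_rep1").sum() > 0).all()

    def test_poisson_limit_at_zero_dispersion(self):
        """phi=0: 10k draws at mu=100 have variance/mean within [0.9, 1.1]."""
        rng = np.random.default_rng(0)
        draws = sd._nb_draw(rng, np.full(10_000, 100.0), 0.0)
        assert 0.9 < draws.var() / draws.mean() < 1.1

    def test_nb_dispersion_inflates_variance(self):
        rng = np.random.default_rng(0)
        draws = sd._nb_draw(rng, np.full(20_000, 100.0), 0.1)
        # var = mu + phi mu^2 = 100 + 1000
        assert draws.var() == pytest.approx(1100, rel=0.1)

    def test_planted_rna_shift_recovered(self):
        """A 1-log2 RNA shift yields an empirical fold change near 2."""
        specs = [
            sd.GeneSpec("hot", "transcriptional", 8.0, 1.0, 0.0, 1.0, False),
        ] + [
            sd.GeneSpec(f"bg{i}", "null", 8.0, 0.0, 0.0, 0.0, False)
            for i in range(99)
        ]
        design = sd.ExperimentDesign(
            conditions=("2iL", "SL"), n_rna_reps=30, n_rfp_reps=2
        )
        sim = sd.SimulationConfig(n_genes=100, seed=4, dispersion=0.0)
        rna, _ = sd.simulate_counts(specs, design, sim)
        ref_cols = rna.samples_for("2iL")
        alt_cols = rna.samples_for("SL")
        ref_cpm = (rna.counts[ref_cols] / rna.counts[ref_cols].sum() * 1e6).loc["hot"]
        alt_cpm = (rna.counts[alt_cols] / rna.counts[alt_cols].sum() * 1e6).loc["hot"]
        assert 1.8 < alt_cpm.mean() / ref_cpm.mean() < 2.2

    def test_negative_dispersion_raises(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(dispersion=-0.1)

    def test_deterministic_and_nonnegative(self):
        specs, design, sim = self._small()
        a_rna, a_rfp = sd.simulate_counts(specs, design, sim)
        b_rna, b_rfp = sd.simulate_counts(specs, design, sim)
        assert a_rna.counts.equals(b_rna.counts) and a_rfp.counts.equals(b_rfp.counts)
        assert (a_rna.counts.values >= 0).all() and (a_rfp.counts.values >= 0).all()


class TestSimulateProteins:
    def _cohort(self, n=400, seed=0, **kw):
        specs = sd.generate_gene_specs(n, seed=seed)
        sim = sd.SimulationConfig(n_genes=n, seed=seed, **kw)
        return specs, sd.ExperimentDesign(conditions=("2iL", "SL")), sim

    def test_no_censoring_no_missing(self):
        specs, design, sim = self._cohort(censor_quantile=0.0)
        pm = sd.simulate_proteins(specs, design, sim)
        assert not pm.intensities.isna().any().any()

    def test_missing_cells_are_low_intensity(self):
        specs, design, sim = self._cohort(censor_quantile=0.2, seed=2)
        full = sd.simulate_proteins(
            specs, design, sd.SimulationConfig(n_genes=400, seed=2, censor_quantile=0.0)
        )
        censored = sd.simulate_proteins(specs, design, sim)
        mask = censored.intensities.isna()
        assert mask.to_numpy().any()
        missing_mean = full.intensities.values[mask.values].mean()
        assert missing_mean < full.intensities.values.mean()

    def test_buffered_genes_protein_stable(self):
        """Planted protein_shift=0: |mean log2FC| below 3 sigma/sqrt(reps)
        for >= 95% of buffered genes."""
        specs, design, sim = self._cohort(
            n=1000, seed=3, censor_quantile=0.0
        )
        pm = sd.simulate_proteins(specs, design, sim)
        buffered = [s.gene_id for s in specs if s.mode == "buffered"]
        a = pm.intensities[pm.samples_for("2iL")].mean(axis=1)
        b = pm.intensities[pm.samples_for("SL")].mean(axis=1)
        fc = (b - a).loc[[f"PG_{g}" for g in buffered]]
        bound = 3 * sim.protein_sigma * np.sqrt(2 / design.n_prot_reps)
        assert (fc.abs() < bound).mean() >= 0.95

    def test_ambiguous_fraction_of_groups(self):
        specs, design, sim = self._cohort()
        pm = sd.simulate_proteins(specs, design, sim, ambiguous_fraction=0.1)
        n_ambig = sum(len(g) == 2 for g in pm.gene_map.values())
        assert n_ambig == round(0.1 * len(specs))

    def test_withdrawal_classes_gate_the_shift(self):
        specs = sd.generate_gene_specs(
            200, {"post_translational": 0.5, "null": 0.5}, seed=6
        )
        design = sd.ExperimentDesign(conditions=("2iL", "SL", "CHL", "PDL"))
        sim = sd.SimulationConfig(n_genes=200, seed=6, censor_quantile=0.0)
        wc = sd.assign_withdrawal_classes(specs, seed=6)
        pm = sd.simulate_proteins(specs, design, sim, withdrawal_classes=wc)
        shifted = {s.gene_id: s for s in specs if s.protein_shift != 0}
        assert set(wc) == set(shifted)
        base = pm.intensities[pm.samples_for("2iL")].mean(axis=1)
        for culture, responding in (("CHL", {"P", "2i"}), ("PDL", {"C", "2i"})):
            fc = pm.intensities[pm.samples_for(culture)].mean(axis=1) - base
            for gene, cls in wc.items():
                observed = fc.loc[f"PG_{gene}"]
                expected = shifted[gene].protein_shift if cls in responding else 0.0
                assert observed == pytest.approx(expected, abs=0.8)

    def test_censor_quantile_one_raises(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(censor_quantile=1.0)


class TestSimulateTranscripts:
    def test_structure_invariants(self, toy_specs, toy_transcripts):
        for t in toy_transcripts:
            assert t.cds.startswith("AUG")
            assert len(t.cds) % 3 == 0
            assert t.cds[-3:] in ("UAA", "UAG", "UGA")
            assert set(t.sequence) <= set("ACGU")
            assert t.tis == len(t.utr5)

    def test_planted_are_found(self, toy_specs, toy_transcripts):
        by_id = {t.gene_id: t for t in toy_transcripts}
        planted = [s for s in toy_specs if s.has_are]
        assert planted, "fixture should plant at least one ARE"
        for s in planted:
            assert sd.ARE_MOTIF in by_id[s.gene_id].utr3

    def test_au_content_concentrates(self):
        """Requested 3'UTR AU=0.8 realizes within ±0.05 over ~1 kb."""
        specs = sd.generate_gene_specs(30, {"null": 1.0}, seed=1)
        cfg = sd.UtrConfig(utr3_len=(1000, 1000), utr3_au=0.8)
        for t in sd.simulate_transcripts(specs, cfg, seed=1):
            au = (t.utr3.count("A") + t.utr3.count("U")) / len(t.utr3)
            assert 0.75 <= au <= 0.85

    def test_impossible_lengths_raise(self):
        with pytest.raises(ValueError):
            sd.UtrConfig(cds_len=(3, 6))

    def test_deterministic(self, toy_specs):
        assert sd.simulate_transcripts(toy_specs, seed=5) == sd.simulate_transcripts(
            toy_specs, seed=5
        )


@pytest.fixture(scope="module")
def reads_and_tx(toy_specs, toy_transcripts):
    weights = {s.gene_id: 1.0 for s in toy_specs}
    reads = sd.simulate_footprints(toy_transcripts, weights, 5000, seed=8)
    return reads, toy_transcripts


class TestSimulateFootprints:

    def test_read_count_conserved(self, reads_and_tx):
        reads, _ = reads_and_tx
        assert len(reads) == 5000

    def test_lengths_in_footprint_range(self, reads_and_tx):
        reads, _ = reads_and_tx
        assert all(28 <= r.length <= 32 for r in reads)

    def test_psite_geometry_dominates(self, reads_and_tx):
        """>= 95% of reads start exactly offset nt upstream of a codon."""
        reads, tx = reads_and_tx
        by_id = {t.gene_id: t for t in tx}
        ok = 0
        for r in reads:
            t = by_id[r.transcript_id]
            delta = r.start + 12 - t.tis
            if delta >= 0 and delta % 3 == 0 and r.start + 12 < t.cds_end:
                ok += 1
        assert ok / len(reads) >= 0.95

    def test_multinomial_weighting(self, toy_specs, toy_transcripts):
        two = toy_transcripts[:2]
        weights = {two[0].gene_id: 9.0, two[1].gene_id: 1.0}
        reads = sd.simulate_footprints(two, weights, 10_000, seed=2)
        n0 = sum(r.transcript_id == two[0].gene_id for r in reads)
        sigma = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(n0 - 9000) < 3 * sigma

    def test_empty_transcripts_raise(self):
        with pytest.raises(ValueError):
            sd.simulate_footprints([], {}, 10)

    def test_all_zero_weights_raise(self, toy_transcripts):
        with pytest.raises(ValueError):
            sd.simulate_footprints(
                toy_transcripts, {t.gene_id: 0.0 for t in toy_transcripts}, 10
            )
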