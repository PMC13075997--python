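import numpy as np
import pandas as pd
import pytest

from splicechrom.annotation import gc_percent
from splicechrom.simulate import (
    SimulationConfig,
    plant_second_cell_line,
    simulate_fragments,
    simulate_genome,
    simulate_psi_table,
    two_proportion_p,
    write_fixture_bundle,
)
from splicechrom.splicing import classify_genes


@pytest.fixture(scope="module")
def small_config():
    # reduced scale for structural checks; class structure unchanged
    return SimulationConfig(seed=123, n_genes=80, genome_size=1_200_000)


@pytest.fixture(scope="module")
def small_sim(small_config):
    return simulate_genome(small_config)


class TestSimulateGenome:
    def test_class_proportions_planted_exactly(self, small_config, small_sim):
        _, _, truth = small_sim
        counts = truth["gene_class"].value_counts()
        assert counts["inactive"] == 40
        assert counts["U2AF2_low_active"] == 28
        assert counts["U2AF2_high_active"] == 12

    def test_intronless_count(self, small_config, small_sim):
        _, _, truth = small_sim
        expected = round(small_config.intronless_fraction * small_config.n_genes)
        assert truth["intronless"].sum() == expected
        intronless = truth[truth["intronless"]]
        assert (intronless["n_exons"] == 1).all()

    def test_genes_nonoverlapping_and_in_bounds(self, small_config, small_sim):
        _, genes, _ = small_sim
        prev_end = 0
        for g in sorted(genes, key=lambda g: g.span.start):
            assert g.span.start >= prev_end
            prev_end = g.span.end
        assert prev_end <= small_config.genome_size

    def test_exon_gc_near_configured_probability(self, small_config, small_sim):
        genome, genes, _ = small_sim
        exon_gc = [gc_percent(e, genome) for g in genes for e in g.exons]
        intron_gc = []
        from splicechrom.annotation import introns_of

        for g in genes:
            intron_gc.extend(gc_percent(i, genome) for i in introns_of(g))
        assert np.mean(exon_gc) == pytest.approx(100 * small_config.gc_prob_exon, abs=2)
        assert np.mean(intron_gc) == pytest.approx(100 * small_config.gc_prob_intron, abs=2)

    def test_same_seed_identical_fasta(self, small_config, tmp_path):
        g1, _, _ = simulate_genome(small_config)
        g2, _, _ = simulate_genome(small_config)
        assert g1.sequences == g2.sequences

    def test_oversized_request_rejected(self):
        config = SimulationConfig(seed=0, n_genes=400, genome_size=100_000)
        with pytest.raises(ValueError, match="genome_size"):
            simulate_genome(config)


class TestSimulateFragments:
    def test_inactive_genes_get_background_only(self, small_config, small_sim):
        genome, genes, truth = small_sim
        config = SimulationConfig(
            seed=9, n_genes=small_config.n_genes, genome_size=small_config.genome_size,
            background_per_kb=0.0,
            u2af2_rpk={"U2AF2_high_active": 20.0, "U2AF2_low_active": 5.0, "inactive": 0.0},
        )
        (frags,) = simulate_fragments(config, genes, truth, "U2AF2", "control", n_replicates=1)
        from splicechrom.occupancy import count_fragments_in

        inactive = truth[truth["gene_class"] == "inactive"]["gene_id"]
        gene_by_id = {g.gene_id: g for g in genes}
        counts = [count_fragments_in(frags, gene_by_id[g].span) for g in inactive]
        # zero rate and zero background: only stray overlaps from neighboring
        # genes' flank placement can touch inactive spans
        assert np.median(counts) == 0

    def test_exon_center_enrichment_matches_fold(self, small_sim, small_config):
        """Fragment-center density per kb in exons vs introns approaches the
        configured enrichment fold at high depth (law of large numbers)."""
        genome, genes, truth = small_sim
        config = SimulationConfig(
            seed=10, n_genes=small_config.n_genes, genome_size=small_config.genome_size,
            background_per_kb=0.0,
            u2af2_rpk={"U2AF2_high_active": 400.0, "U2AF2_low_active": 400.0, "inactive": 400.0},
        )
        (frags,) = simulate_fragments(config, genes, truth, "U2AF2", "control", n_replicates=1)
        starts, ends = frags.by_chrom[config.chrom_name]
        centers = (starts + ends) // 2
        from splicechrom.annotation import introns_of

        exon_bp = intron_bp = 0
        exon_hits = intron_hits = 0
        centers.sort()
        for g in genes:
            for e in g.exons:
                exon_bp += e.length
                exon_hits += np.searchsorted(centers, e.end) - np.searchsorted(centers, e.start)
            for i in introns_of(g):
                intron_bp += i.length
                intron_hits += np.searchsorted(centers, i.end) - np.searchsorted(centers, i.start)
        ratio = (exon_hits / exon_bp) / (intron_hits / intron_bp)
        assert ratio == pytest.approx(config.exon_enrichment_fold["U2AF2"], rel=0.1)

    def test_rnase_condition_reduces_sensitive_genes(self, small_config, small_sim):
        genome, genes, truth = small_sim
        control = simulate_fragments(small_config, genes, truth, "U2AF2", "control")
        rnase = simulate_fragments(small_config, genes, truth, "U2AF2", "rnase")
        from splicechrom.occupancy import count_fragments_in

        gene_by_id = {g.gene_id: g for g in genes}
        sens = truth[truth["rnase_sensitive"]]
        ratios = []
        for gid in sens["gene_id"]:
            span = gene_by_id[gid].span
            c = np.mean([count_fragments_in(f, span) for f in control])
            r = np.mean([count_fragments_in(f, span) for f in rnase])
            if c > 0:
                ratios.append(r / c)
        assert np.median(ratios) == pytest.approx(small_config.rnase_fold, abs=0.15)

    def test_deterministic_under_seed(self, small_config, small_sim):
        _, genes, truth = small_sim
        a = simulate_fragments(small_config, genes, truth, "MNase", "control", n_replicates=1)
        b = simulate_fragments(small_config, genes, truth, "MNase", "control", n_replicates=1)
        np.testing.assert_array_equal(a[0].by_chrom[small_config.chrom_name][0],
                                      b[0].by_chrom[small_config.chrom_name][0])


class TestSimulatePsi:
    def test_planted_skipped_recovered_with_high_power(self, small_config, small_sim):
        _, _, truth = small_sim
        table = simulate_psi_table(small_config, truth)
        classes = classify_genes(table).set_index("gene_id")
        planted = truth[truth["exon_class"] == "skipped"]
        recovered = classes.loc[
            [g for g in planted["gene_id"] if g in classes.index], "exon_class"
        ]
        assert (recovered == "skipped").mean() > 0.9

    def test_null_significance_near_alpha(self):
        config = SimulationConfig(seed=77, n_genes=40, genome_size=600_000)
        # all-null truth: every tested gene unchanged
        truth = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(2000)],
                "exon_class": "unchanged",
                "intron_class": "unchanged",
            }
        )
        table = simulate_psi_table(config, truth)
        frac = (table["p_value"] < 0.05).mean()
        n = len(table)
        tol = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) <= tol + 0.005  # binomial bounds + test discreteness

    def test_concordance_parameter_recovered(self, small_config):
        config = SimulationConfig(seed=42, n_genes=3000, genome_size=60_000_000)
        rng = np.random.default_rng(0)
        truth = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(3000)],
                "exon_class": rng.choice(
                    ["skipped", "included", "MXE", "unchanged"], size=3000,
                    p=[0.2, 0.1, 0.05, 0.65],
                ),
                "intron_class": "unchanged",
            }
        )
        second = plant_second_cell_line(config, truth)
        errors = truth["exon_class"].isin(["skipped", "included", "MXE"])
        still_error = second.loc[errors, "exon_class"].isin(["skipped", "included", "MXE"])
        assert still_error.mean() == pytest.approx(config.concordance_error, abs=0.03)
        clean = truth["exon_class"] == "unchanged"
        still_clean = second.loc[clean, "exon_class"] == "unchanged"
        assert still_clean.mean() == pytest.approx(config.concordance_no_error, abs=0.03)

    def test_two_proportion_p_calibration(self):
        rng = np.random.default_rng(3)
        ps = [
            two_proportion_p(int(rng.binomial(200, 0.5)), 200, int(rng.binomial(200, 0.5)), 200)
            for _ in range(3000)
        ]
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.015

    def test_powered_event_significant(self):
        rng = np.random.default_rng(4)
        hits = sum(
            two_proportion_p(int(rng.binomial(200, 0.65)), 200, int(rng.binomial(200, 0.35)), 200) < 0.05
            for _ in range(200)
        )
        assert hits >= 199  # ΔPSI 0.3 at depth 200: power > 0.99


class TestFixtureBundle:
    def test_bundle_writes_and_reloads_through_pipeline_types(self, tmp_path):
        config = SimulationConfig(seed=5, n_genes=40, genome_size=700_000)
        manifest = write_fixture_bundle(config, tmp_path / "bundle")
        from splicechrom.annotation import GenomeSequence, read_annotation
        from splicechrom.coverage import FragmentSet, read_sample_sheet

        genome = GenomeSequence.from_fasta(tmp_path / "bundle" / "genome.fa")
        genes = read_annotation(tmp_path / "bundle" / "genes.bed12")
        sheet = read_sample_sheet(tmp_path / "bundle" / "sample_sheet.tsv")
        assert genome.total_size == config.genome_size
        assert len(genes) == config.n_genes
        fs = FragmentSet.from_bed(tmp_path / "bundle" / sheet.iloc[0]["fragments_path"])
        assert fs.n_fragments > 0
        truth = pd.read_csv(tmp_path / "bundle" / "truth.tsv", sep="\t")
        assert len(truth) == config.n_genes
        assert set(manifest["files"]) >= {"genome.fa", "genes.bed12", "truth.tsv"}

    def test_same_seed_same_manifest(self, tmp_path):
        config = SimulationConfig(seed=6, n_genes=30, genome_size=600_000)
        m1 = write_fixture_bundle(config, tmp_path / "b1")
        m2 = write_fixture_bundle(config, tmp_path / "b2")
        assert m1 == m2

    def test_refuses_nonempty_outdir_without_force(self, tmp_path):
        config = SimulationConfig(seed=7, n_genes=30, genome_size=600_000)
        out = tmp_path / "b"
        write_fixture_bundle(config, out)
        with pytest.raises(FileExistsError):
            write_fixture_bundle(config, out)
        write_fixture_bundle(config, out, force=True)
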