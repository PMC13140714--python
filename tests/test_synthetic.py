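"""Synthetic study generator: determinism, planted structure, ground truth."""

import numpy as np
import pandas as pd
import pytest

from betacross import enrichment, io, synthetic
from betacross.config import ConfigError, SimulationConfig
from betacross.directionality import classify_change, explode_probe_genes, group_mean_beta
from betacross.preprocess import m_to_beta


def _cfg(**kw):
    base = dict(n_probes=1000, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestManifest:
    def test_degenerate_proportions_put_every_probe_in_open_sea(self):
        props = {c: 0.0 for c in ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf")}
        props["OpenSea"] = 1.0
        man = synthetic.generate_manifest(_cfg(island_proportions=props))
        assert (man["Relation_to_Island"] == "OpenSea").all()

    def test_same_seed_gives_identical_manifest(self, tmp_path):
        m1 = synthetic.generate_manifest(_cfg())
        m2 = synthetic.generate_manifest(_cfg())
        io.write_manifest(m1, tmp_path / "a.tsv")
        io.write_manifest(m2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_island_counts_match_binomial_expectation(self):
        props = {c: 0.0 for c in ("N_Shore", "S_Shore", "N_Shelf", "S_Shelf")}
        props.update(Island=0.3, OpenSea=0.7)
        man = synthetic.generate_manifest(_cfg(n_probes=10_000, island_proportions=props))
        n_island = (man["Relation_to_Island"] == "Island").sum()
        sd = np.sqrt(10_000 * 0.3 * 0.7)
        assert abs(n_island - 3000) < 3 * sd

    def test_many_to_many_gene_mappings_present(self):
        man = synthetic.generate_manifest(_cfg(n_probes=3000))
        mapping = explode_probe_genes(man)
        per_probe = mapping.groupby("probe_id")["gene"].nunique()
        per_gene = mapping.groupby("gene")["probe_id"].nunique()
        assert (per_probe >= 2).any()
        assert (per_gene >= 2).any()
        assert (man["UCSC_RefGene_Name"] == "").any()  # unannotated probes exist

    def test_invalid_proportions_rejected(self):
        props = {c: 0.5 for c in synthetic.ISLAND_CATEGORIES}
        with pytest.raises(ConfigError, match="sum to 1"):
            synthetic.generate_manifest(_cfg(island_proportions=props))


class TestGenerateBeta:
    def test_null_configuration_has_no_dmps_and_equal_means(self):
        cfg = _cfg(frac_dmp=0, frac_crossing_low_high=0, frac_crossing_high_low=0)
        man = synthetic.generate_manifest(cfg)
        _, _, truth = synthetic.generate_beta(man, cfg)
        assert not truth["is_dmp"].any()
        assert (truth["planted_class"] == "stable").all()
        assert np.array_equal(
            truth["true_mean_beta_control"], truth["true_mean_beta_case"]
        )

    def test_values_in_unit_interval_or_missing(self, small_sim):
        _, _, beta, _, _ = small_sim
        vals = beta.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        assert ok.all()

    def test_planted_crossing_means_straddle_the_cutoff(self, small_sim):
        _, _, _, _, truth = small_sim
        lh = truth[truth["planted_class"] == "low_to_high"]
        hl = truth[truth["planted_class"] == "high_to_low"]
        assert len(lh) and len(hl)
        assert (lh["true_mean_beta_control"] < 0.5).all()
        assert (lh["true_mean_beta_case"] >= 0.5).all()
        assert (hl["true_mean_beta_control"] >= 0.5).all()
        assert (hl["true_mean_beta_case"] < 0.5).all()

    def test_stable_probes_never_cross(self, small_sim):
        _, _, _, _, truth = small_sim
        stable = truth[truth["planted_class"] == "stable"]
        crosses = (stable["true_mean_beta_control"] < 0.5) != (
            stable["true_mean_beta_case"] < 0.5
        )
        assert not crosses.any()

    def test_determinism_and_truth_covers_every_probe(self, small_sim):
        cfg, man, beta, sheet, truth = small_sim
        beta2, sheet2, truth2 = synthetic.generate_beta(man, cfg)
        pd.testing.assert_frame_equal(beta, beta2)
        pd.testing.assert_frame_equal(sheet, sheet2)
        pd.testing.assert_frame_equal(truth, truth2)
        assert list(truth["probe_id"]) == list(beta.index)
        assert truth["probe_id"].is_unique

    def test_beta_m_consistency_of_ground_truth(self, small_sim):
        _, _, _, _, truth = small_sim
        back = m_to_beta(truth["true_mean_m_control"].to_numpy())
        assert np.allclose(back, truth["true_mean_beta_control"], atol=1e-12)

    def test_missing_rate_within_three_standard_errors(self):
        cfg = _cfg(n_probes=3000, missing_rate=0.05, frac_high_missing_probes=0.0)
        man = synthetic.generate_manifest(cfg)
        beta, _, _ = synthetic.generate_beta(man, cfg)
        frac = beta.isna().to_numpy().mean()
        n = beta.size
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se

    def test_high_missing_probes_exceed_eighty_percent(self, small_sim):
        cfg, _, beta, _, _ = small_sim
        missing = beta.isna().mean(axis=1)
        k = round(cfg.frac_high_missing_probes * cfg.n_probes)
        assert (missing > 0.8).sum() == k

    def test_dataset_blocks_partition_samples(self, small_sim):
        cfg, _, _, sheet, _ = small_sim
        assert sheet["dataset_id"].nunique() == cfg.n_datasets
        assert len(sheet) == cfg.n_control + cfg.n_case

    def test_too_few_samples_refused(self):
        cfg = _cfg(n_control=2, n_case=1)
        man = synthetic.generate_manifest(cfg)
        with pytest.raises(ValueError, match="at least 4"):
            synthetic.generate_beta(man, cfg)

    def test_observed_group_means_recover_planted_crossing_class(self):
        """Monte-Carlo recovery of the planted class at effect 2, n = 30 + 30."""
        correct = total = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_probes=500, n_control=30, n_case=30, effect_size_m=2.0, seed=seed
            )
            man = synthetic.generate_manifest(cfg)
            beta, sheet, truth = synthetic.generate_beta(man, cfg)
            means = group_mean_beta(beta, sheet)
            truth = truth.set_index("probe_id")
            crossing = truth[truth["planted_class"].isin(["low_to_high", "high_to_low"])]
            for probe, planted in crossing["planted_class"].items():
                got = classify_change(
                    means.loc[probe, "mean_beta_control"], means.loc[probe, "mean_beta_case"]
                )
                total += 1
                correct += got == planted
        assert correct / total >= 0.90


class TestGenerateGmt:
    def test_single_full_universe_term_has_rich_factor_one(self, small_sim, tmp_path):
        cfg, man, _, _, truth = small_sim
        genes = sorted(set(explode_probe_genes(man)["gene"]))
        sets = {"T1": ("full universe", genes)}
        io.write_gmt(sets, tmp_path / "u.gmt")
        db = io.load_gmt(tmp_path / "u.gmt")
        rec = enrichment.ora_test(
            set(genes), db, universe=set(genes), pvalue_cutoff=1.1, qvalue_cutoff=1.1
        )
        # query = universe: the term's RichFactor is k/K = 1, FoldEnrichment 1
        assert rec.iloc[0]["rich_factor"] == 1.0
        assert rec.iloc[0]["fold_enrichment"] == 1.0

    def test_gmt_roundtrip_lossless(self, small_sim, tmp_path):
        cfg, man, _, _, truth = small_sim
        sets = synthetic.generate_gmt(man, 10, 2, cfg, truth=truth, path=tmp_path / "g.gmt")
        assert io.load_gmt(tmp_path / "g.gmt") == sets

    def test_more_enriched_than_terms_rejected(self, small_sim):
        cfg, man, _, _, truth = small_sim
        with pytest.raises(ConfigError):
            synthetic.generate_gmt(man, 2, 3, cfg, truth=truth)

    def test_planted_term_beats_random_term_of_equal_size(self):
        """A term seeded with planted-DMP genes should out-rank a random one."""
        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(n_probes=1500, seed=seed)
            man = synthetic.generate_manifest(cfg)
            _, _, truth = synthetic.generate_beta(man, cfg)
            sets = synthetic.generate_gmt(man, 20, 1, cfg, truth=truth)
            mapping = explode_probe_genes(man)
            dmp_probes = set(truth.loc[truth["is_dmp"], "probe_id"])
            query = set(mapping.loc[mapping["probe_id"].isin(dmp_probes), "gene"])
            universe = set(mapping["gene"])
            rec = enrichment.ora_test(query, sets, universe=universe, pvalue_cutoff=1.1, qvalue_cutoff=1.1)
            table = rec.attrs.get("all_terms", rec).set_index("term_id")
            planted_p = table.loc["T0001", "p_value"]
            planted_size = table.loc["T0001", "K"]
            others = table.drop(index="T0001")
            closest = (others["K"] - planted_size).abs().idxmin()
            wins += planted_p < others.loc[closest, "p_value"]
        assert wins >= 19
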