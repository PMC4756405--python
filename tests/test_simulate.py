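"""Generator behaviour: determinism, truncation, moments, truth tables."""

import numpy as np
import pandas as pd
import pytest

from heteroseq import (
    ConfigError,
    SimConfig,
    fpkm,
    gen_annotation,
    gen_f1,
    gen_phenotypes,
    gen_transcriptomes,
    simulate_all,
)


def _flat_config(**kw):
    base = dict(seed=1, n_genes=500, mean_library_size=100_000)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = _flat_config(seed=9)
        a, b = gen_phenotypes(cfg), gen_phenotypes(cfg)
        pd.testing.assert_frame_equal(a, b)
        s1, s2 = simulate_all(cfg), simulate_all(cfg)
        pd.testing.assert_frame_equal(s1.counts.counts, s2.counts.counts)
        pd.testing.assert_frame_equal(s1.pileup, s2.pileup)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        pd.testing.assert_frame_equal(s1.hormones, s2.hormones)
        pd.testing.assert_frame_equal(s1.annotation, s2.annotation)

    def test_different_seed_differs(self):
        a = gen_phenotypes(_flat_config(seed=1))
        b = gen_phenotypes(_flat_config(seed=2))
        assert not a["value"].equals(b["value"])

    def test_substreams_independent_of_each_other(self):
        # regenerating one component alone matches the bundled run
        cfg = _flat_config(seed=5)
        bundle = simulate_all(cfg)
        cm, snps, truth = gen_transcriptomes(cfg)
        pd.testing.assert_frame_equal(
            bundle.counts.counts[["P1", "P2"]], cm.counts
        )


class TestPhenotypes:
    def test_zero_sd_gives_exact_group_means(self):
        params = {("trait_x", 2): {ln: (50.0, 0.0) for ln in ("P1", "P2", "F1")}}
        cfg = _flat_config(phenotype_group_params=params)
        table = gen_phenotypes(cfg)
        assert (table["value"] == 50.0).all()

    def test_negative_sd_rejected(self):
        params = {("t", 2): {"P1": (1.0, -0.5), "P2": (1.0, 1.0), "F1": (1.0, 1.0)}}
        with pytest.raises(ConfigError):
            gen_phenotypes(_flat_config(phenotype_group_params=params))

    def test_values_positive_despite_noisy_group(self):
        params = {("t", 2): {ln: (1.0, 5.0) for ln in ("P1", "P2", "F1")}}
        table = gen_phenotypes(_flat_config(phenotype_group_params=params))
        assert (table["value"] > 0).all()

    def test_large_sample_mean_near_group_mean(self):
        # law of large numbers: n = 10,000, mean 100, SD 10
        params = {("t", 2): {ln: (100.0, 10.0) for ln in ("P1", "P2", "F1")}}
        cfg = _flat_config(
            phenotype_group_params=params, n_individuals_per_line=10_000
        )
        table = gen_phenotypes(cfg)
        for _, grp in table.groupby("line"):
            assert abs(grp["value"].mean() - 100.0) < 3 * 10.0 / np.sqrt(10_000)


class TestTranscriptomes:
    def test_poisson_limit_variance_matches_mean(self):
        # dispersion -> 0: per-gene variance ~ mean across many genes
        cfg = _flat_config(
            n_genes=100_000, nb_dispersion=0.0, log_expr_sigma=0.0,
            frac_de_parents=0.0, frac_snp_genes=0.0, mean_library_size=1_000_000,
        )
        cm, _, _ = gen_transcriptomes(cfg)
        counts = cm.counts["P1"].to_numpy()
        # all genes share one mean => pooled moments estimate it
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_dispersion_inflates_variance(self):
        cfg = _flat_config(
            n_genes=50_000, nb_dispersion=0.2, log_expr_sigma=0.0,
            frac_de_parents=0.0, frac_snp_genes=0.0,
            mean_library_size=5_000_000,
        )
        cm, _, _ = gen_transcriptomes(cfg)
        counts = cm.counts["P1"].to_numpy()
        m = counts.mean()
        # gamma-Poisson: var = m + dispersion * m^2
        assert counts.var() == pytest.approx(m + 0.2 * m**2, rel=0.1)

    def test_no_de_fraction_means_empty_de_truth(self):
        _, _, truth = gen_transcriptomes(_flat_config(frac_de_parents=0.0))
        assert truth["is_de"].sum() == 0
        assert (truth["log2fc_p1_vs_p2"] == 0).all()

    def test_snp_gene_fraction_within_binomial_interval(self):
        cfg = _flat_config(n_genes=10_000, frac_snp_genes=0.31)
        _, snps, truth = gen_transcriptomes(cfg)
        n_snp_genes = (truth["n_snps"] > 0).sum()
        se = np.sqrt(0.31 * 0.69 * 10_000)
        assert abs(n_snp_genes - 3100) < 4 * se
        assert snps["gene_id"].nunique() == n_snp_genes

    def test_zero_genes_rejected(self):
        with pytest.raises(ConfigError):
            gen_transcriptomes(_flat_config(n_genes=0))

    def test_truth_covers_every_gene_once(self):
        cm, _, truth = gen_transcriptomes(_flat_config())
        assert list(truth["gene_id"]) == list(cm.gene_ids)
        assert not truth["gene_id"].duplicated().any()


class TestF1:
    def test_no_ase_all_ratios_half(self):
        cfg = _flat_config(frac_ase=0.0)
        _, _, truth = gen_transcriptomes(cfg)
        with_snp = truth["n_snps"] > 0
        assert (truth.loc[with_snp, "true_allelic_ratio"] == 0.5).all()
        assert truth.loc[~with_snp, "true_allelic_ratio"].isna().all()

    def test_high_coverage_ratio_converges_to_five_sixths(self):
        # binomial mean: ase_fold 5 => allelic ratio 5/6
        cfg = _flat_config(
            n_genes=400, frac_snp_genes=1.0, frac_ase=1.0, ase_fold=5.0,
            site_coverage_mean=500.0,
        )
        cm, snps, truth = gen_transcriptomes(cfg)
        _, _, pileup = gen_f1(cfg, truth, snps)
        toward_p1 = truth.set_index("gene_id")["true_allelic_ratio"] > 0.5
        per_gene = pileup.groupby("gene_id")[["count_F1"]].sum()
        p1_reads = (
            pileup.merge(snps, on=["chrom", "pos", "gene_id"])
            .query("base == allele_p1")
            .groupby("gene_id")["count_F1"].sum()
        )
        ratio = p1_reads / per_gene["count_F1"]
        folded = np.where(toward_p1.loc[ratio.index], ratio, 1 - ratio)
        assert folded.mean() == pytest.approx(5 / 6, abs=0.01)

    def test_additivity_without_ase_or_nonadditive_genes(self):
        # expected F1 FPKM equals mean parental FPKM gene by gene
        cfg = _flat_config(
            n_genes=300, frac_ase=0.0, frac_nonadditive=0.0,
            frac_de_parents=0.3, nb_dispersion=0.0,
            mean_library_size=2_000_000, log_expr_sigma=0.5,
        )
        cm, snps, truth = gen_transcriptomes(cfg)
        f1_counts, f1_lib, _ = gen_f1(cfg, truth, snps)
        f_p1 = fpkm(cm.counts["P1"].to_numpy(), cm.lengths.to_numpy(),
                    float(cm.lib_sizes["P1"]))
        f_p2 = fpkm(cm.counts["P2"].to_numpy(), cm.lengths.to_numpy(),
                    float(cm.lib_sizes["P2"]))
        f_f1 = fpkm(f1_counts.to_numpy(), cm.lengths.to_numpy(), float(f1_lib))
        mpv = (f_p1 + f_p2) / 2
        keep = mpv > 0
        rel = f_f1[keep] / mpv[keep]
        # CLT: average relative deviation shrinks with depth
        assert rel.mean() == pytest.approx(1.0, abs=0.02)

    def test_truth_missing_gene_rejected(self):
        cfg = _flat_config(frac_snp_genes=1.0, n_genes=50)
        _, snps, truth = gen_transcriptomes(cfg)
        from heteroseq import DataError

        with pytest.raises(DataError):
            gen_f1(cfg, truth.iloc[:-1], snps)


class TestAnnotation:
    def test_zero_terms_warns_and_returns_empty(self):
        cfg = _flat_config(n_go_terms=0)
        _, _, truth = gen_transcriptomes(cfg)
        with pytest.warns(UserWarning):
            ann, terms = gen_annotation(cfg, truth)
        assert len(ann) == 0 and len(terms) == 0

    def test_term_sizes_bounded_and_members_unique(self):
        cfg = _flat_config(n_genes=1000)
        _, _, truth = gen_transcriptomes(cfg)
        ann, terms = gen_annotation(cfg, truth)
        sizes = ann.groupby("term_id").size()
        assert len(sizes) == cfg.n_go_terms
        assert not ann.duplicated(["term_id", "gene_id"]).any()
        assert set(ann["gene_id"]) <= set(truth["gene_id"])

    def test_odds_ratio_one_gives_uniform_enrichment_p(self):
        # 500 regenerated annotations at odds 1: overrepresentation
        # p-values of the DE list behave as a null.  Small discrete
        # terms make p super-uniform (P(p <= t) <= t), so the valid
        # uniformity check is one-sided: the empirical CDF must not
        # exceed the uniform CDF beyond sampling noise.
        from dataclasses import replace

        from heteroseq import hypergeom_tail

        cfg = _flat_config(
            n_genes=400, frac_de_parents=0.2, n_go_terms=1,
            frac_enriched_terms=1.0, enriched_odds=1.0,
        )
        _, _, truth = gen_transcriptomes(cfg)
        de = set(truth.loc[truth["is_de"], "gene_id"])
        ps = []
        for rep in range(500):
            ann, _ = gen_annotation(replace(cfg, seed=1000 + rep), truth)
            members = set(ann["gene_id"])
            ps.append(
                hypergeom_tail(
                    len(members & de), len(de), len(members), cfg.n_genes
                )
            )
        ps = np.sort(np.array(ps))
        ecdf_excess = np.max(np.arange(1, len(ps) + 1) / len(ps) - ps)
        assert ecdf_excess < 0.07  # ~ KS noise at 500 draws
        assert ps.mean() >= 0.45  # not degenerate at 1

    def test_enriched_terms_recruit_de_genes(self):
        cfg = _flat_config(
            n_genes=1000, frac_de_parents=0.2, frac_enriched_terms=0.5,
            enriched_odds=20.0,
        )
        _, _, truth = gen_transcriptomes(cfg)
        ann, terms = gen_annotation(cfg, truth)
        de_genes = set(truth.loc[truth["is_de"], "gene_id"])
        frac_de_in = ann.merge(terms, on="term_id").assign(
            de=lambda d: d["gene_id"].isin(de_genes)
        ).groupby("enriched")["de"].mean()
        assert frac_de_in[True] > 2 * frac_de_in[False]
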