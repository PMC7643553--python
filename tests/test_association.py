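"""SNP filtering, heterozygosity, kinship, REML and the Q+K scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from palmlnc.association import (
    QKMixedModel,
    filter_snps,
    kinship_matrix,
    mlm_scan,
    observed_heterozygosity,
    reml_variance_components,
    snps_in_lncrna,
)
from palmlnc.containers import GenotypeTable, LncRnaLocus, TranscriptModel
from palmlnc.simulate import SimulationConfig, simulate_phenotypes


def _table(dosage_rows, pos=None):
    dosage = np.array(dosage_rows, dtype=np.int8)
    m, n = dosage.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "chrom": "chr1",
            "pos": pos if pos is not None else np.arange(m) * 100 + 50,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return GenotypeTable(snps, dosage, [f"i{j}" for j in range(n)])


M = GenotypeTable.MISSING


class TestSnpFilters:
    def test_maf_boundary_strict(self):
        # 10 individuals, one het: MAF = 1/20 = 0.05 exactly -> removed
        t = _table([[1] + [0] * 9])
        assert filter_snps(t).n_snps == 0

    def test_call_rate_boundary_strict(self):
        # 8/10 called -> call rate 0.80 exactly -> removed
        t = _table([[1, 1, 1, 0, 0, 0, 0, 0, M, M]])
        assert filter_snps(t).n_snps == 0

    def test_hand_counted_example_retained(self):
        # AA x8, AG x1, missing x1: MAF = 1/18, call rate 0.9
        t = _table([[0] * 8 + [1, M]])
        assert t.maf()[0] == pytest.approx(1 / 18)
        assert t.call_rate()[0] == pytest.approx(0.9)
        kept = filter_snps(t)
        assert kept.n_snps == 1  # 1/18 > 0.05 and 0.9 > 0.8

    def test_empty_table_passes_through(self):
        t = _table(np.empty((0, 4), dtype=np.int8))
        assert filter_snps(t).n_snps == 0

    def test_maf_het_callrate_invariant_to_allele_swap(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = M
        t = _table(d)
        swapped = d.copy()
        swapped[d == 0] = 2
        swapped[d == 2] = 0
        s = _table(swapped)
        np.testing.assert_allclose(t.maf(), s.maf())
        np.testing.assert_allclose(t.heterozygosity(), s.heterozygosity())
        np.testing.assert_allclose(t.call_rate(), s.call_rate())


class TestHeterozygosity:
    def test_examples(self):
        assert observed_heterozygosity([1, 1, 1]) == 1.0
        assert observed_heterozygosity([0, 0, 0, 1]) == 0.25
        assert observed_heterozygosity([0, 1, M, M]) == 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            observed_heterozygosity([M, M])


class TestSnpsInLncrna:
    def _loci_and_tx(self):
        tx = {
            "t1": TranscriptModel("t1", "chr1", "+", [(100, 200), (300, 400)]),
            "t2": TranscriptModel("t2", "chr1", "-", [(350, 450)]),
        }
        loci = [
            LncRnaLocus("L1", "chr1", "+", 100, 400, ["t1"], "lincRNA"),
            LncRnaLocus("L2", "chr1", "-", 350, 450, ["t2"], "lincRNA"),
        ]
        return loci, tx

    def test_exon_intron_context(self):
        loci, tx = self._loci_and_tx()
        t = _table([[0, 1, 2]] * 2, pos=[150, 250])
        rec = snps_in_lncrna(t, loci, tx)
        by_id = rec.set_index("snp_id")
        assert by_id.loc["s0", "context"] == "exon"     # inside exon 1 of t1
        assert by_id.loc["s1", "context"] == "intron"   # between exons, inside span

    def test_snp_in_two_overlapping_loci_gets_two_records(self):
        loci, tx = self._loci_and_tx()
        t = _table([[0, 1, 2]], pos=[380])
        rec = snps_in_lncrna(t, loci, tx)
        assert len(rec) == 2 and set(rec["locus_id"]) == {"L1", "L2"}

    def test_outside_any_locus_no_record(self):
        loci, tx = self._loci_and_tx()
        t = _table([[0, 1, 2]], pos=[900])
        assert len(snps_in_lncrna(t, loci, tx)) == 0


class TestKinship:
    def test_duplicated_individual_duplicates_row(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        d[:, 1] = d[:, 0]
        k = kinship_matrix(_table(d))
        np.testing.assert_allclose(k[0], k[1])
        assert k[0, 1] == pytest.approx(k[0, 0])
        np.testing.assert_allclose(k, k.T)

    def test_unrelated_off_diagonal_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.5, 5000)
        d = rng.binomial(2, p[:, None], size=(5000, 30)).astype(np.int8)
        k = kinship_matrix(_table(d))
        off = k[~np.eye(30, dtype=bool)]
        assert abs(off.mean()) < 0.05
        assert np.median(np.diag(k)) == pytest.approx(1.0, abs=0.15)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            kinship_matrix(_table([[0, 0, 0], [2, 2, 2]]))


class TestReml:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(120)
        sg2, se2 = reml_variance_components(y, np.eye(120))
        # with K = I only the total is identified; it equals the sample variance
        assert sg2 + se2 == pytest.approx(np.var(y, ddof=1), rel=1e-3)

    def test_recovers_zero_and_half_heritability(self):
        cfg = SimulationConfig(seed=21, n_individuals=300, n_snps=600, missing_rate=0.0)
        from palmlnc.simulate import simulate_genotypes

        g = simulate_genotypes(cfg)
        k = kinship_matrix(g.table)
        for h2 in (0.0, 0.5):
            cfg_h = SimulationConfig(
                seed=21, n_individuals=300, n_snps=600, missing_rate=0.0, h2=h2
            )
            ests = []
            for rep in range(20):
                ph = simulate_phenotypes(
                    cfg_h, g.table, g.q_matrix, causal={},
                    rng=np.random.default_rng([rep, 5]),
                )
                sg2, se2 = reml_variance_components(
                    ph.y.to_numpy(), k, g.q_matrix.to_numpy()
                )
                ests.append(sg2 / (sg2 + se2))
            assert np.mean(ests) == pytest.approx(h2, abs=0.08)


class TestScan:
    def test_scan_with_zero_genetic_variance_matches_ols(self):
        """sigma_g^2 = 0 must reproduce ordinary-regression p-values."""
        rng = np.random.default_rng(6)
        n = 80
        y = rng.standard_normal(n)
        x = rng.integers(0, 3, n).astype(float)
        model = QKMixedModel(y, np.eye(n))
        fit = model.fit()
        fit = fit.__class__(  # force the no-polygenic limit
            model=model, lambda_=1e-12, sigma_g2=0.0, sigma_e2=1.0,
            beta=fit.beta, restricted_loglik=fit.restricted_loglik,
        )
        res = fit.scan(x[None, :])
        slope, intercept, r, p_ols, se = stats.linregress(x, y)
        assert res["p_value"].iloc[0] == pytest.approx(p_ols, abs=1e-8)
        assert res["effect"].iloc[0] == pytest.approx(slope, abs=1e-8)

    def test_permutation_invariance(self, genotypes_200):
        cfg, g = genotypes_200
        k = kinship_matrix(g.table)
        ph = simulate_phenotypes(cfg, g.table, g.q_matrix)
        sub = g.table.subset(np.arange(g.table.n_snps) < 30)
        base = mlm_scan(ph.y.to_numpy(), sub, g.q_matrix.to_numpy(), k)

        rng = np.random.default_rng(9)
        perm = rng.permutation(g.table.n_individuals)
        sub_p = GenotypeTable(sub.snps, sub.dosage[:, perm], [sub.individuals[i] for i in perm])
        scan_p = mlm_scan(
            ph.y.to_numpy()[perm], sub_p, g.q_matrix.to_numpy()[perm], k[np.ix_(perm, perm)]
        )
        a = base.set_index("snp_id")["p_value"]
        b = scan_p.set_index("snp_id")["p_value"]
        np.testing.assert_allclose(a[b.index], b, rtol=1e-6)

    def test_monomorphic_snp_skipped(self, genotypes_200, caplog):
        cfg, g = genotypes_200
        k = kinship_matrix(g.table)
        ph = simulate_phenotypes(cfg, g.table, g.q_matrix)
        mono = _table([[1] * g.table.n_individuals])
        model = QKMixedModel(ph.y.to_numpy(), k, g.q_matrix.to_numpy()).fit()
        with caplog.at_level("WARNING"):
            res = model.scan(mono)
        assert len(res) == 0

    def test_neg_log10_transform(self):
        assert -np.log10(5.01e-08) == pytest.approx(7.3, abs=0.05)

    def test_qk_model_controls_structured_confounding(self):
        """With subpopulation phenotype shifts and no causal SNPs, the Q+K
        scan's inflation is closer to 1 than a covariate-free regression's."""
        from palmlnc.simulate import simulate_genotypes

        cfg = SimulationConfig(seed=31, n_individuals=200, n_snps=1200, fst=0.15, h2=0.3)
        g = simulate_genotypes(cfg)
        split = 400
        k = kinship_matrix(g.table.subset(np.arange(cfg.n_snps) < split))
        test = g.table.subset(np.arange(cfg.n_snps) >= split)
        ph = simulate_phenotypes(
            cfg, g.table, g.q_matrix, causal={},
            subpop_effects=np.linspace(-1.5, 1.5, cfg.n_subpops),
        )
        y = ph.y.to_numpy()
        qk = mlm_scan(y, test, g.q_matrix.to_numpy(), k)
        chi2_qk = stats.chi2.ppf(1 - qk["p_value"], 1)

        naive_p = []
        d = test.imputed_dosage()
        for j in range(d.shape[0]):
            if np.ptp(d[j]) == 0:
                continue
            naive_p.append(stats.linregress(d[j], y).pvalue)
        chi2_naive = stats.chi2.ppf(1 - np.array(naive_p), 1)
        lam_qk = np.median(chi2_qk) / stats.chi2.ppf(0.5, 1)
        lam_naive = np.median(chi2_naive) / stats.chi2.ppf(0.5, 1)
        assert abs(lam_qk - 1) < abs(lam_naive - 1)
        assert lam_naive > 1.2  # the confounding is real


def test_model_summary_mentions_components(genotypes_200):
    cfg, g = genotypes_200
    k = kinship_matrix(g.table)
    ph = simulate_phenotypes(cfg, g.table, g.q_matrix)
    res = QKMixedModel(ph.y.to_numpy(), k, g.q_matrix.to_numpy()).fit()
    text = res.summary()
    assert "sigma_g^2" in text and "REML" in text
    assert 0 <= res.heritability <= 1
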