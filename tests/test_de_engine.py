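import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from mirimpact.de_engine import (
    DEEngine,
    bh_adjust,
    estimate_dispersions,
    nb_glm_test,
    tmm_normalize,
)


def bh_brute_force(p):
    """O(m^2) step-up BH: q_i = min over {j: p_j >= p_i} of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * pj / np.sum(p <= pj) for pj in p if pj >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


def nb_matrix(rng, m, n, mean_lo=1.0, mean_hi=1000.0, phi_lo=0.02, phi_hi=0.8):
    base = np.exp(rng.uniform(np.log(mean_lo), np.log(mean_hi), m))
    phi = np.exp(rng.uniform(np.log(phi_lo), np.log(phi_hi), m))
    mu = np.tile(base[:, None], (1, n))
    return rng.poisson(rng.gamma(1 / phi[:, None], mu * phi[:, None])), base, phi


class TestBHAdjust:
    def test_three_value_example(self):
        assert bh_adjust(np.array([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_singleton_identity(self):
        assert bh_adjust(np.array([0.5])) == pytest.approx([0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([np.nan]))

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    def test_matches_brute_force_and_preserves_order(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert q == pytest.approx(bh_brute_force(p), abs=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], abs=1e-12
        )


class TestTMM:
    def test_identical_samples_unit_factors(self, rng):
        y, _, _ = nb_matrix(rng, 50, 1)
        counts = np.tile(y, (1, 4))
        norm = tmm_normalize(counts)
        assert norm.scale_factor == pytest.approx(np.ones(4))

    def test_doubling_absorbed_by_library_size(self, rng):
        y, _, _ = nb_matrix(rng, 200, 1)
        counts = np.hstack([y, 2 * y])
        norm = tmm_normalize(counts)
        assert norm.scale_factor == pytest.approx([1.0, 1.0], abs=1e-8)
        assert norm.library_size[1] == 2 * norm.library_size[0]

    def test_tripling_one_sample_triples_effective_size(self, rng):
        y, _, _ = nb_matrix(rng, 300, 8)
        eff0 = tmm_normalize(y).effective_size
        y2 = y.copy()
        y2[:, 3] *= 3
        eff1 = tmm_normalize(y2).effective_size
        assert eff1[3] / eff0[3] == pytest.approx(3.0, rel=0.01)

    def test_geometric_mean_one(self, rng):
        y, _, _ = nb_matrix(rng, 150, 6)
        y[: 75, 0] *= 2  # asymmetric composition shift
        norm = tmm_normalize(y)
        assert np.exp(np.mean(np.log(norm.scale_factor))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_normalize(np.array([[0, 5], [0, 3]]))


class TestDispersions:
    def test_poisson_truth_near_zero(self, rng):
        n = 200
        base = np.exp(rng.uniform(np.log(5), np.log(500), 300))
        y = rng.poisson(np.tile(base[:, None], (1, n)))
        labels = np.arange(n) < n // 2
        phi = estimate_dispersions(y, labels, tmm_normalize(y))
        assert np.median(phi) <= 0.05

    def test_nb_dispersion_recovered(self, rng):
        n = 200
        base = np.exp(rng.uniform(np.log(5), np.log(500), 300))
        mu = np.tile(base[:, None], (1, n))
        y = rng.poisson(rng.gamma(1 / 0.4, mu * 0.4))
        labels = np.arange(n) < n // 2
        phi = estimate_dispersions(y, labels, tmm_normalize(y), shrink=0.0)
        assert 0.25 <= np.median(phi) <= 0.6

    def test_degenerate_feature_gets_common_dispersion(self, rng):
        y, _, _ = nb_matrix(rng, 50, 20)
        y[0] = 0
        labels = np.arange(20) < 10
        phi = estimate_dispersions(y, labels, tmm_normalize(y))
        assert np.isfinite(phi).all()
        assert phi[0] > 0

    def test_empty_class_rejected(self, rng):
        y, _, _ = nb_matrix(rng, 10, 10)
        with pytest.raises(ValueError):
            estimate_dispersions(y, np.zeros(10, bool), tmm_normalize(y))


class TestNBGLM:
    def test_null_pvalues_uniform(self, rng):
        y, _, _ = nb_matrix(rng, 2000, 100)
        eng = DEEngine(y)
        labels = np.zeros(100, bool)
        labels[rng.choice(100, 50, replace=False)] = True
        res = eng.result(labels)
        p = res.raw_p[res.tested]
        assert kstest(p, "uniform").statistic < 0.05

    def test_exchangeable_null_calibration(self, rng):
        """Fraction of raw p below alpha within 3 binomial SDs of alpha."""
        y, _, _ = nb_matrix(rng, 1500, 80)
        eng = DEEngine(y)
        labels = np.zeros(80, bool)
        labels[rng.choice(80, 24, replace=False)] = True
        res = eng.result(labels)
        p = res.raw_p[res.tested]
        for alpha in (0.01, 0.05, 0.1):
            sd = np.sqrt(alpha * (1 - alpha) / p.size)
            assert abs(np.mean(p < alpha) - alpha) < 3 * sd

    def test_power_at_strong_fold_change(self, rng):
        m, n = 200, 200
        base = np.exp(rng.uniform(np.log(5), np.log(500), m))
        lfc = rng.choice([-2.0, 2.0], m)
        mu = np.tile(base[:, None], (1, n))
        labels = np.arange(n) >= 100
        mu[:, labels] *= 2.0 ** lfc[:, None]
        y = rng.poisson(rng.gamma(1 / 0.2, mu * 0.2))
        res = DEEngine(y).result(labels)
        assert np.mean(res.q[res.tested] < 0.05) >= 0.90
        # logFC signs recovered
        sign_ok = np.sign(res.logfc[res.tested]) == np.sign(lfc[res.tested])
        assert np.mean(sign_ok) > 0.95

    def test_constant_feature_no_signal(self, rng):
        y, _, _ = nb_matrix(rng, 20, 30)
        y[0] = 7
        labels = np.arange(30) < 15
        res = DEEngine(y, min_total_count=0).result(labels)
        assert res.raw_p[0] == 1.0
        assert res.logfc[0] == 0.0

    def test_N_monotone_in_threshold(self, rng):
        m, n = 300, 100
        base = np.exp(rng.uniform(np.log(5), np.log(500), m))
        mu = np.tile(base[:, None], (1, n))
        labels = np.arange(n) < 50
        mu[:50, labels] *= 2.0 ** rng.choice([-1.5, 1.5], 50)[:, None]
        y = rng.poisson(rng.gamma(1 / 0.3, mu * 0.3))
        eng_loose = DEEngine(y, fdr_threshold=0.10)
        eng_tight = DEEngine(y, fdr_threshold=0.01)
        assert eng_tight.count(labels) <= eng_loose.count(labels)

    def test_dimension_mismatch_rejected(self, rng):
        y, _, _ = nb_matrix(rng, 10, 10)
        eng = DEEngine(y)
        with pytest.raises(ValueError):
            eng.result(np.zeros(7, bool))

    def test_low_count_features_excluded_from_N(self, rng):
        y, _, _ = nb_matrix(rng, 30, 20)
        y[0] = 0
        eng = DEEngine(y, min_total_count=10)
        labels = np.arange(20) < 10
        res = eng.result(labels)
        assert not res.tested[0]
        assert np.isnan(res.raw_p[0])


class TestEdgeRConcordance:
    """Cross-validation of the DE engine against edgeR's glmLRT."""

    def test_logfc_and_pvalues_concordant(self, tmp_path, rng):
        from scipy.stats import spearmanr
        from mirimpact.synthetic_data import GeneEffect, SimulationConfig, simulate_cohort
        from mirimpact.io_cohort import build_contexts

        cfg = SimulationConfig(
            seed=9, n_patients=80, n_features=150, n_genes=2,
            mutation_freqs=[0.4, 0.2],
            effects=[GeneEffect("GENE01", 40, 1.2)],
        )
        cohort, mm, _ = simulate_cohort(cfg)
        ctx = {c.gene: c for c in build_contexts(mm, cohort)}["GENE01"]
        res = DEEngine(cohort.counts).result(ctx.labels)

        counts_path = tmp_path / "counts.tsv"
        cohort.counts.to_csv(counts_path, sep="\t")
        labels_path = tmp_path / "labels.txt"
        np.savetxt(labels_path, ctx.labels.astype(int), fmt="%d")
        out_path = tmp_path / "edger.tsv"
        script = tmp_path / "run.R"
        script.write_text(
            f"""suppressMessages(library(edgeR))
y <- as.matrix(read.delim("{counts_path}", row.names=1))
g <- factor(scan("{labels_path}", quiet=TRUE))
dge <- DGEList(counts=y, group=g); dge <- calcNormFactors(dge)
design <- model.matrix(~g)
dge <- estimateDisp(dge, design)
fit <- glmFit(dge, design); lrt <- glmLRT(fit)
write.table(data.frame(feature=rownames(y), logFC=lrt$table$logFC, p=lrt$table$PValue),
            "{out_path}", sep="\\t", quote=FALSE, row.names=FALSE)
"""
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        edger = pd.read_csv(out_path, sep="\t").set_index("feature")
        mine = res.to_frame().set_index("feature")[res.tested]
        shared = mine.index.intersection(edger.index)
        logfc_r = np.corrcoef(mine.loc[shared, "logFC"], edger.loc[shared, "logFC"])[0, 1]
        p_rho = spearmanr(mine.loc[shared, "raw_p"], edger.loc[shared, "p"]).statistic
        assert logfc_r > 0.95
        assert p_rho > 0.90
        edger_n = int((bh_adjust(edger.loc[shared, "p"].to_numpy()) < 0.05).sum())
        assert abs(res.N - edger_n) <= 10
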