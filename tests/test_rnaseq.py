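"""Unit and property tests for normalization, QC, and distance analysis."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from her2het import rnaseq
from her2het.rnaseq import (
    ExpressionMatrix,
    associate,
    euclidean_distance,
    filter_zero_genes,
    intra_pair_distances,
    log_cpm,
    patient_aggregate,
    pc2_outlier_filter,
    pca_scores,
    responder_split,
    tmm_factors,
    treatment_distances,
)


def tmm_oracle(counts: np.ndarray, m_trim=0.30, a_trim=0.05) -> np.ndarray:
    """Independent direct-formula TMM implementation (plain loops).

    Reference: library whose 75th count/libsize percentile is closest to the
    mean; per library, trimmed (by M and A ranks, average ranks for ties)
    inverse-variance-weighted mean of M; factors rescaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    lib = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - np.mean(f75))))
    ref, n_ref = counts[:, ref_j], lib[ref_j]
    out = []
    for j in range(counts.shape[1]):
        obs, n_obs = counts[:, j], lib[j]
        both = (obs > 0) & (ref > 0)
        o, r = obs[both], ref[both]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        if np.max(np.abs(m)) < 1e-6:
            out.append(1.0)
            continue
        n = len(m)
        lo_m = math.floor(n * m_trim) + 1
        lo_a = math.floor(n * a_trim) + 1
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (
            (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        )
        out.append(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    out = np.array(out)
    return out / np.exp(np.mean(np.log(out)))


def random_count_matrix(rng, n_genes=300, n_samples=5):
    shape = (n_genes, n_samples)
    base = rng.negative_binomial(5, 0.02, size=shape).astype(np.int64)
    base *= rng.random(shape) < 0.9  # sprinkle zeros
    df = pd.DataFrame(
        base,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return df[df.sum(axis=1) > 0]


def make_matrix(counts: pd.DataFrame, meta: "pd.DataFrame | None" = None):
    if meta is None:
        meta = pd.DataFrame(
            {"patient_id": list(counts.columns), "timepoint": "pre"},
            index=counts.columns,
        )
    return ExpressionMatrix(counts, meta)


class TestFilterZeroGenes:
    def test_drops_exactly_allzero_genes(self):
        counts = pd.DataFrame(
            np.array([[1, 0], [0, 0], [2, 3], [0, 0]]),
            index=list("abcd"), columns=["s1", "s2"],
        )
        out = filter_zero_genes(make_matrix(counts))
        assert list(out.counts.index) == ["a", "c"]
        assert list(out.counts.columns) == ["s1", "s2"]

    def test_identity_without_zero_genes(self):
        counts = random_count_matrix(np.random.default_rng(0))
        out = filter_zero_genes(make_matrix(counts))
        assert out.counts.equals(counts)

    def test_all_zero_matrix_yields_empty(self):
        counts = pd.DataFrame(np.zeros((4, 2), dtype=int),
                              index=list("abcd"), columns=["s1", "s2"])
        out = filter_zero_genes(make_matrix(counts))
        assert out.counts.shape == (0, 2)


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(60, 200)
        counts = pd.DataFrame({"a": col, "b": col.copy()})
        assert np.allclose(tmm_factors(counts).values, 1.0)

    def test_doubled_library_unit_factors(self):
        # doubling every count doubles the library size, so all gene-wise
        # M values are 0 and composition is unchanged: factors stay 1
        rng = np.random.default_rng(2)
        a = rng.poisson(50, 300) + 1
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.allclose(tmm_factors(counts).values, [1.0, 1.0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_count_matrix(rng, n_samples=int(rng.integers(3, 8)))
        mine = tmm_factors(counts).values
        ref = tmm_oracle(counts.values)
        assert np.allclose(mine, ref, atol=1e-9)

    def test_geometric_mean_one(self):
        counts = random_count_matrix(np.random.default_rng(3))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f.values))) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_is_approximate(self):
        # inverse-variance weights depend on absolute counts, so scaling one
        # library perturbs its factor slightly (matches edgeR); M values and
        # CPMs are invariant at the percent level, not to machine precision
        rng = np.random.default_rng(4)
        counts = random_count_matrix(rng, n_samples=4)
        f1 = tmm_factors(counts)
        scaled = counts.copy()
        scaled["s1"] = scaled["s1"] * 9
        f2 = tmm_factors(scaled)
        assert np.allclose(f1.values, f2.values, rtol=1e-2)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against Bioconductor edgeR::calcNormFactors."""
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript expected on PATH"
        rng = np.random.default_rng(11)
        counts = random_count_matrix(rng, n_genes=400, n_samples=5)
        csv = tmp_path / "counts.tsv"
        counts.to_csv(csv, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.delim("{csv}", row.names=1))\n'
            'cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n")\n'
        )
        res = subprocess.run([rscript, str(script)], capture_output=True, text=True,
                             check=True)
        ref = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(tmm_factors(counts).values, ref, atol=1e-9)

    def test_fewer_than_two_samples_rejected(self):
        counts = pd.DataFrame({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestLogCPM:
    def test_direct_formula(self):
        counts = pd.DataFrame({"a": [100, 999900], "b": [50, 999950]},
                              index=["g1", "g2"])
        m = make_matrix(counts)
        factors = pd.Series([1.0, 1.0], index=["a", "b"])
        norm = log_cpm(m, factors)
        assert norm.values.loc["g1", "a"] == pytest.approx(np.log2(101), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 50]}, index=["g1", "g2"])
        factors = pd.Series([2.0, 0.5], index=["a", "b"])
        norm = log_cpm(make_matrix(counts), factors)
        assert (norm.values.loc["g1"] == 0.0).all()

    def test_cpm_ratio_invariance(self):
        counts = pd.DataFrame({"a": [10, 90], "b": [30, 70]}, index=["g1", "g2"])
        doubled = counts * 2
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        n1 = log_cpm(make_matrix(counts), f)
        n2 = log_cpm(make_matrix(doubled), f)
        assert np.allclose(n1.values.values, n2.values.values)

    def test_normalized_cpm_invariant_under_library_scaling(self):
        rng = np.random.default_rng(8)
        counts = random_count_matrix(rng, n_samples=4)
        n1 = log_cpm(make_matrix(counts), tmm_factors(counts))
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 5
        n2 = log_cpm(make_matrix(scaled), tmm_factors(scaled))
        assert np.allclose(n1.values.values, n2.values.values, atol=2e-2)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame(rng.normal(size=(20, 6)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(6)])
        scores, var_frac = pca_scores(values, n_components=3)
        x = values.values.T - values.values.T.mean(axis=0)
        cov = x.T @ x
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(3):
            ref = x @ v[:, order[k]]
            got = scores.iloc[:, k].values
            assert np.allclose(np.abs(got), np.abs(ref), atol=1e-8)
        assert var_frac.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(var_frac) <= 1e-12)

    def test_duplicate_samples_share_scores(self):
        rng = np.random.default_rng(10)
        half = rng.normal(size=(30, 3))
        values = pd.DataFrame(np.hstack([half, half]),
                              columns=["a", "b", "c", "a2", "b2", "c2"])
        scores, _ = pca_scores(values, n_components=2)
        assert np.allclose(scores.loc["a"].values, scores.loc["a2"].values)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(rng.normal(size=(40, 8)))
        values.columns = [f"s{j}" for j in range(8)]
        s1, _ = pca_scores(values, 3)
        s2, _ = pca_scores(values * 1.0, 3)
        assert np.allclose(s1.values, s2.values)

    def test_single_sample_rejected(self):
        values = pd.DataFrame({"only": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pca_scores(values, 1)


class TestPC2Filter:
    def _scores(self, pc2):
        return pd.DataFrame({"PC1": np.zeros(len(pc2)), "PC2": pc2},
                            index=[f"s{i}" for i in range(len(pc2))])

    def test_clean_cohort_keeps_everything(self):
        rng = np.random.default_rng(13)
        report = pc2_outlier_filter(self._scores(rng.normal(size=100)))
        assert len(report.excluded) == 0
        assert len(report.retained) == 100

    def test_planted_outlier_excluded(self):
        rng = np.random.default_rng(14)
        pc2 = rng.normal(size=100)
        pc2[17] = pc2.std() * 30  # far beyond 5 SD even after inflation
        report = pc2_outlier_filter(self._scores(pc2))
        assert list(report.excluded["sample"]) == ["s17"]

    def test_exact_threshold_retained(self):
        # symmetric pair at exactly the 5-SD boundary: strict > keeps both
        base = np.zeros(40)
        base[:20] = 1.0
        base[20:] = -1.0
        v = base / np.std(base, ddof=1) * 5.0
        report = pc2_outlier_filter(self._scores(v - v.mean()))
        assert len(report.excluded) == 0

    def test_all_identical_no_exclusions(self):
        report = pc2_outlier_filter(self._scores(np.ones(10)))
        assert len(report.excluded) == 0

    def test_single_pass_not_iterative(self):
        # a moderate outlier inflates the SD enough to shield itself; a
        # single-pass rule must keep it (iterative refitting would not)
        pc2 = np.concatenate([np.random.default_rng(15).normal(size=20), [8.0]])
        sd = pc2.std(ddof=1)
        assert np.abs(pc2 - pc2.mean()).max() < 5 * sd
        report = pc2_outlier_filter(self._scores(pc2))
        assert len(report.excluded) == 0


class TestAggregationAndDistance:
    def _norm(self, values, meta):
        factors = pd.Series(1.0, index=values.columns)
        return rnaseq.NormalizedMatrix(values, factors, meta)

    def test_patient_aggregate_means_pairs(self):
        values = pd.DataFrame(
            {"p1_a": [2.0, 4.0], "p1_b": [4.0, 8.0], "p2_a": [1.0, 1.0]},
            index=["g1", "g2"],
        )
        meta = pd.DataFrame(
            {"patient_id": ["p1", "p1", "p2"], "timepoint": ["pre"] * 3},
            index=values.columns,
        )
        agg, missing = patient_aggregate(self._norm(values, meta), "pre")
        assert agg.loc["p1", "g1"] == pytest.approx(3.0)
        assert agg.loc["p2", "g2"] == pytest.approx(1.0)  # single-biopsy passthrough
        assert missing == []

    def test_euclidean_examples(self):
        assert euclidean_distance([1, 2], [1, 2]) == 0.0
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)
        rng = np.random.default_rng(16)
        a, b = rng.normal(size=50), rng.normal(size=50)
        ref = math.sqrt(math.fsum((x - y) ** 2 for x, y in zip(a, b)))
        assert euclidean_distance(a, b) == pytest.approx(ref, rel=1e-12)
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_treatment_distance_zero_when_post_equals_pre_mean(self):
        values = pd.DataFrame(
            {"p1_pre1": [1.0, 3.0], "p1_pre2": [3.0, 5.0], "p1_post": [2.0, 4.0]},
            index=["g1", "g2"],
        )
        meta = pd.DataFrame(
            {"patient_id": ["p1"] * 3, "timepoint": ["pre", "pre", "post"]},
            index=values.columns,
        )
        records, missing = treatment_distances(self._norm(values, meta))
        assert records.loc[0, "distance"] == pytest.approx(0.0)
        assert missing == []

    def test_missing_post_reported_not_dropped_silently(self):
        values = pd.DataFrame({"p1_pre1": [1.0], "p2_pre1": [1.0], "p2_post": [2.0]},
                              index=["g1"])
        meta = pd.DataFrame(
            {"patient_id": ["p1", "p2", "p2"], "timepoint": ["pre", "pre", "post"]},
            index=values.columns,
        )
        records, missing = treatment_distances(self._norm(values, meta))
        assert list(records["patient_id"]) == ["p2"]
        assert missing == ["p1"]

    def test_intra_pair_and_single_biopsy_na(self):
        values = pd.DataFrame(
            {"p1_pre1": [0.0], "p1_pre2": [3.0], "p2_pre1": [1.0]}, index=["g1"]
        )
        meta = pd.DataFrame(
            {"patient_id": ["p1", "p1", "p2"], "timepoint": ["pre"] * 3},
            index=values.columns,
        )
        records, single = intra_pair_distances(self._norm(values, meta))
        by_pid = records.set_index("patient_id")
        assert by_pid.loc["p1", "distance"] == pytest.approx(3.0)
        assert np.isnan(by_pid.loc["p2", "distance"])
        assert single == ["p2"]

    def test_distance_invariant_to_gene_order_and_zero_genes(self):
        rng = np.random.default_rng(17)
        counts = random_count_matrix(rng, n_genes=100, n_samples=4)
        meta = pd.DataFrame(
            {"patient_id": ["p1", "p1", "p1", "p2"],
             "timepoint": ["pre", "pre", "post", "pre"]},
            index=counts.columns,
        )
        norm1 = rnaseq.normalize(ExpressionMatrix(counts, meta))
        d1, _ = treatment_distances(norm1)
        shuffled = counts.sample(frac=1.0, random_state=3)
        zeros = pd.DataFrame(0, index=[f"z{i}" for i in range(5)], columns=counts.columns)
        counts2 = pd.concat([shuffled, zeros])
        norm2 = rnaseq.normalize(ExpressionMatrix(counts2, meta))
        d2, _ = treatment_distances(norm2)
        assert d1.loc[0, "distance"] == pytest.approx(d2.loc[0, "distance"], rel=1e-12)


class TestResponderSplit:
    def test_distances_1_to_8(self):
        records = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(8)],
             "distance": np.arange(1.0, 9.0), "kind": "PRE_TO_POST"}
        )
        out = responder_split(records)
        assert (out["responder"] == "WEAK").sum() == 2
        assert set(out.loc[out["responder"] == "WEAK", "patient_id"]) == {"p0", "p1"}

    def test_hundred_distinct_gives_25_weak(self):
        rng = np.random.default_rng(18)
        records = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(100)],
             "distance": rng.permutation(100).astype(float), "kind": "PRE_TO_POST"}
        )
        out = responder_split(records)
        assert (out["responder"] == "WEAK").sum() == 25

    def test_all_equal_all_weak(self):
        records = pd.DataFrame(
            {"patient_id": list("abcd"), "distance": [2.0] * 4, "kind": "PRE_TO_POST"}
        )
        out = responder_split(records)
        assert (out["responder"] == "WEAK").all()

    def test_too_few_records_rejected(self):
        records = pd.DataFrame({"patient_id": list("abc"), "distance": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            responder_split(records)


def mannwhitney_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = stats.rankdata(pooled)

    def u_stat(idx_a):
        r = ranks[list(idx_a)].sum()
        return r - n_a * (n_a + 1) / 2

    u_obs = u_stat(range(n_a))
    us = np.array([u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)])
    mean_u = len(a) * len(b) / 2
    return np.mean(np.abs(us - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)


class TestAssociate:
    def test_perfect_correlation(self):
        r, p = associate([1, 2, 3, 4], [2, 4, 6, 8], "continuous")
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_identical_groups_maximal_p(self):
        x = [1, 2, 3, 4, 5, 6]
        g = ["a", "b"] * 3
        stat, p = associate(x, g, "two_group")
        assert p > 0.5

    def test_two_group_matches_enumeration(self):
        a = np.array([1.3, 2.1, 9.4, 4.2])
        b = np.array([5.5, 7.7, 8.8])
        x = np.concatenate([a, b])
        g = ["a"] * 4 + ["b"] * 3
        _, p = associate(x, g, "two_group")
        assert p == pytest.approx(mannwhitney_enumeration_p(a, b), abs=1e-12)

    def test_paired_detects_consistent_shift(self):
        x = np.arange(1.0, 11.0)
        y = x + np.array([0.5, 0.7, 0.9, 0.6, 0.8, 0.55, 0.65, 0.75, 0.85, 0.95])
        _, p = associate(x, y, "paired")
        assert p == pytest.approx(2 / 1024, abs=1e-12)  # all signs negative, exact null

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            associate([1, 2], [3, 4], "continuous")
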