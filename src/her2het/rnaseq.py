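"""Paired-biopsy RNA-seq normalization, QC, and transcriptomic distances.

The normalization pipeline follows common bulk RNA-seq practice: drop genes
with zero counts across all samples, compute trimmed-mean-of-M-values (TMM)
library-composition factors (Robinson & Oshlack 2010, as implemented in
edgeR), and work in log2(TMM-CPM + 1) space.  Sample QC removes biopsies
whose PC2 score lies more than 5 standard deviations from the cohort mean
(treatment typically dominates PC1, so gross technical artifacts surface on
treatment-unrelated components).  Treatment response is quantified per
patient as the Euclidean distance between the mean of the (up to two)
pretreatment biopsies and the residual-tumor sample, and patients are split
into weak (lowest quartile of distance) and strong (the rest)
transcriptomic responders.

Differential-expression testing itself is out of scope here; the fold-change
and adjusted-p cutoffs used alongside these analyses are recorded as
constants (`DE_CUTOFFS`) for provenance only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fish import Timepoint

__all__ = [
    "DE_CUTOFFS",
    "ExpressionMatrix",
    "NormalizedMatrix",
    "QCReport",
    "filter_zero_genes",
    "tmm_factors",
    "log_cpm",
    "normalize",
    "pca_scores",
    "pc2_outlier_filter",
    "patient_aggregate",
    "euclidean_distance",
    "treatment_distances",
    "intra_pair_distances",
    "responder_split",
    "associate",
]

# Recorded differential-expression thresholds used in the companion DESeq2
# analyses (not implemented here): adjusted p < 0.05 throughout; |fold
# change| > 8 for pre-vs-post comparisons, > 1.5 for pretreatment-group
# comparisons.
DE_CUTOFFS = {
    "padj": 0.05,
    "abs_fc_pre_post": 8.0,
    "abs_fc_pretreatment": 1.5,
}

# PC2 QC exclusion threshold (|PC2 - mean| > N_SD_QC * SD).
N_SD_QC = 5.0
# Exact rank-test null used up to this per-group size; normal approximation
# with continuity correction beyond.
EXACT_RANK_TEST_MAX_N = 25

REQUIRED_METADATA = ["patient_id", "timepoint"]


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts plus per-sample metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``metadata`` is indexed by sample id and must carry at least
    ``patient_id`` and ``timepoint`` ('pre'/'post'); optional columns used
    downstream: ``biopsy_index`` ('1'/'2'/'surgical'), ``pcr``, ``het``,
    ``hr_status``, ``rcb_score``, ``age``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("sample identifiers must be unique")
        if self.counts.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples lack metadata: {sorted(missing)[:5]}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class NormalizedMatrix:
    """log2(TMM-CPM + 1) expression values with the factors that made them."""

    values: pd.DataFrame
    tmm_factors: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = float(np.mean(np.log(self.tmm_factors.values)))
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QCReport:
    """Outcome of the PC-based sample exclusion."""

    excluded: pd.DataFrame  # sample, pc_value, mean, sd
    retained: list[str]
    component: str = "PC2"
    n_sd: float = N_SD_QC


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero counts across all samples."""
    keep = m.counts.sum(axis=1) > 0
    return ExpressionMatrix(m.counts.loc[keep], m.metadata)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    m_trim: float,
    a_trim: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2^f).

    Implements the trimmed, inverse-variance-weighted mean of gene-wise
    log-ratios M over genes expressed in both libraries, with double
    trimming on M (log-ratio) and A (absolute expression).
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[fin], abs_e[fin], var[fin]
    if log_r.size == 0:
        raise ValueError("no genes expressed in both libraries")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * m_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * a_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        raise ValueError("trimming removed all genes; loosen m_trim/a_trim")
    f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0 ** f)


def tmm_factors(
    m: "ExpressionMatrix | pd.DataFrame",
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference library is the sample whose 75th count/library-size
    percentile is closest to the cohort mean of that percentile.  Effective
    library size is library size x factor; factors near 1 indicate similar
    RNA composition.
    """
    counts = m.counts if isinstance(m, ExpressionMatrix) else m
    x = counts.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total count")
    # drop all-zero rows (they carry no information and skew quantiles)
    x = x[x.sum(axis=1) > 0, :]
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = x[:, ref_idx]
    factors = np.array(
        [_tmm_pair_factor(x[:, j], ref, m_trim, a_trim) for j in range(x.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(m: ExpressionMatrix, factors: pd.Series) -> NormalizedMatrix:
    """log2(count / (library size x TMM factor) x 1e6 + 1)."""
    factors = factors.reindex(m.counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and aligned to samples")
    lib = m.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    eff = lib * factors
    values = np.log2(m.counts.divide(eff, axis=1) * 1e6 + 1.0)
    return NormalizedMatrix(values=values, tmm_factors=factors, metadata=m.metadata)


def normalize(m: ExpressionMatrix) -> NormalizedMatrix:
    """Zero-gene filter + TMM + log2-CPM in one step."""
    filtered = filter_zero_genes(m)
    return log_cpm(filtered, tmm_factors(filtered))


def pca_scores(
    n: "NormalizedMatrix | pd.DataFrame",
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of samples on gene-centered expression.

    Genes are centered across samples; no unit-variance scaling.  Component
    signs are fixed by making each component's largest-magnitude gene
    loading positive, so results are reproducible across linear-algebra
    backends.  Returns (scores, variance fractions).
    """
    values = n.values if isinstance(n, NormalizedMatrix) else n
    samples = list(values.columns)
    if len(samples) < 2:
        raise ValueError("PCA requires at least two samples")
    max_rank = min(values.shape[0], len(samples) - 1)
    if n_components > max_rank:
        raise ValueError(f"n_components must be <= {max_rank}")
    x = values.values.T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float(np.sum(s**2))
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            scores[:, k] *= -1.0
            loadings[k] *= -1.0
    var_frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    score_df = pd.DataFrame(
        scores, index=samples, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    return score_df, var_frac


def pc2_outlier_filter(
    scores: pd.DataFrame,
    component: str = "PC2",
    n_sd: float = N_SD_QC,
) -> QCReport:
    """Exclude samples whose ``component`` score is > n_sd SDs from the mean.

    Applied in a single pass: mean and SD are computed over all samples,
    candidates included.  Strictly-greater comparison, so a sample sitting
    exactly at the threshold is retained.
    """
    if component not in scores.columns:
        raise ValueError(f"score table has no column {component!r}")
    if len(scores) < 3:
        raise ValueError("outlier filter requires at least 3 samples")
    v = scores[component].astype(float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        mask = pd.Series(False, index=scores.index)
    else:
        mask = (v - mean).abs() > n_sd * sd
    excluded = pd.DataFrame(
        {
            "sample": scores.index[mask],
            "pc_value": v[mask].values,
            "mean": mean,
            "sd": sd,
        }
    ).reset_index(drop=True)
    retained = list(scores.index[~mask])
    return QCReport(excluded=excluded, retained=retained, component=component, n_sd=n_sd)


def patient_aggregate(
    n: NormalizedMatrix,
    timepoint: "str | Timepoint",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient mean expression over available biopsies at a timepoint.

    Patient-level aggregation keeps one observation per patient (the mean of
    the two pretreatment biopsies when both were profiled).  Returns
    (patients x genes matrix, patients in the metadata with no sample at the
    timepoint).
    """
    tp = Timepoint.parse(timepoint).value
    meta = n.metadata
    at_tp = meta[meta["timepoint"].astype(str).str.lower() == tp]
    groups = at_tp.groupby("patient_id").groups
    rows, index = [], []
    for pid in sorted(groups, key=str):
        sample_ids = list(groups[pid])
        rows.append(n.values[sample_ids].mean(axis=1).values)
        index.append(str(pid))
    all_patients = set(meta["patient_id"].astype(str))
    missing = sorted(all_patients - set(index))
    agg = pd.DataFrame(rows, index=index, columns=n.values.index)
    return agg, missing


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Plain Euclidean distance between two aligned expression vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _project(values: pd.DataFrame, space: str, n_pcs: int) -> pd.DataFrame:
    """Optionally replace genes by top principal-component coordinates."""
    if space == "genes":
        return values
    if space == "pcs":
        scores, _ = pca_scores(values, n_components=n_pcs)
        return scores.T
    raise ValueError("space must be 'genes' or 'pcs'")


def treatment_distances(
    n: NormalizedMatrix,
    space: str = "genes",
    n_pcs: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient pre-to-post Euclidean distance.

    Distance between the patient's mean pretreatment expression and the
    posttreatment (residual tumor) sample, in log2(TMM-CPM+1) space over all
    retained genes by default (``space='pcs'`` uses top principal-component
    coordinates instead).  Returns (records, patients lacking a pre or post
    sample).
    """
    values = _project(n.values, space, n_pcs)
    proj = NormalizedMatrix(values, n.tmm_factors, n.metadata)
    pre_agg, _ = patient_aggregate(proj, Timepoint.PRE)
    meta = n.metadata
    post_meta = meta[meta["timepoint"].astype(str).str.lower() == "post"]
    post_by_patient = post_meta.groupby(post_meta["patient_id"].astype(str)).groups
    rows, missing = [], []
    patients = sorted(set(meta["patient_id"].astype(str)))
    for pid in patients:
        has_pre = pid in pre_agg.index
        posts = [str(s) for s in post_by_patient.get(pid, [])]
        if not has_pre or not posts:
            missing.append(pid)
            continue
        if len(posts) > 1:
            raise ValueError(f"patient {pid!r} has multiple post samples")
        d = euclidean_distance(pre_agg.loc[pid].values, values[posts[0]].values)
        rows.append({"patient_id": pid, "distance": d, "kind": "PRE_TO_POST"})
    return pd.DataFrame(rows, columns=["patient_id", "distance", "kind"]), missing


def intra_pair_distances(n: NormalizedMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Euclidean distance between the two pretreatment biopsies per patient.

    Patients with a single pretreatment biopsy get an NA distance and are
    also listed in the single-biopsy report.
    """
    meta = n.metadata
    pre_meta = meta[meta["timepoint"].astype(str).str.lower() == "pre"]
    rows, single = [], []
    for pid, grp in pre_meta.groupby("patient_id"):
        pid = str(pid)
        ids = list(grp.index)
        if len(ids) == 2:
            d = euclidean_distance(n.values[ids[0]].values, n.values[ids[1]].values)
            rows.append({"patient_id": pid, "distance": d, "kind": "INTRA_PRE_PAIR"})
        elif len(ids) == 1:
            single.append(pid)
            rows.append({"patient_id": pid, "distance": np.nan, "kind": "INTRA_PRE_PAIR"})
        else:
            raise ValueError(f"patient {pid!r} has {len(ids)} pretreatment biopsies")
    return pd.DataFrame(rows, columns=["patient_id", "distance", "kind"]), single


def responder_split(records: pd.DataFrame) -> pd.DataFrame:
    """Label pre-to-post distances WEAK (lowest quartile) or STRONG (rest).

    The threshold is the 25th percentile under the linear-interpolation
    quantile convention; distances at or below it are WEAK.
    """
    if len(records) < 4:
        raise ValueError("responder split requires at least 4 records")
    d = records["distance"].astype(float).values
    threshold = float(np.percentile(d, 25))
    out = records.copy()
    out["responder"] = np.where(d <= threshold, "WEAK", "STRONG")
    out.attrs["weak_threshold"] = threshold
    return out


def associate(
    values: Sequence[float],
    covariate: Sequence,
    kind: str,
) -> tuple[float, float]:
    """Patient-level association test, returning (statistic, two-sided p).

    ``kind='continuous'``: Pearson correlation with t-based p.
    ``kind='two_group'``: Mann-Whitney U between the two covariate groups
    (exact null up to n=25 per group when there are no ties, normal
    approximation with continuity correction otherwise).
    ``kind='paired'``: Wilcoxon matched-pairs signed-rank on (values -
    covariate) with the same exact/approximate switch-over.
    """
    x = np.asarray(values, dtype=float)
    if kind == "continuous":
        y = np.asarray(covariate, dtype=float)
        if x.size < 3:
            raise ValueError("continuous association requires n >= 3")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if kind == "two_group":
        g = np.asarray(covariate)
        levels = pd.unique(g)
        if len(levels) != 2:
            raise ValueError("two_group covariate must have exactly 2 levels")
        a = x[g == levels[0]]
        b = x[g == levels[1]]
        if min(a.size, b.size) < 3:
            raise ValueError("two_group association requires n >= 3 per group")
        no_ties = np.unique(x).size == x.size
        method = (
            "exact"
            if no_ties and max(a.size, b.size) <= EXACT_RANK_TEST_MAX_N
            else "asymptotic"
        )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if kind == "paired":
        y = np.asarray(covariate, dtype=float)
        if x.size != y.size:
            raise ValueError("paired vectors must have equal length")
        if x.size < 3:
            raise ValueError("paired association requires n >= 3")
        diffs = x - y
        nz = diffs[diffs != 0]
        if nz.size == 0:
            return 0.0, 1.0
        no_ties = np.unique(np.abs(nz)).size == nz.size
        method = "exact" if no_ties and nz.size <= EXACT_RANK_TEST_MAX_N else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method, correction=True)
        return float(res.statistic), float(res.pvalue)
    raise ValueError("kind must be 'continuous', 'two_group', or 'paired'")
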