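"""Synthetic cohorts with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed, emits a ground-truth
table alongside the data, and writes its output in the exact input schema
of the consuming module.  The default configurations emulate the study
design the package targets: a neoadjuvant HER2-positive cohort of three
patient groups (non-heterogeneous with pathologic complete response n=64,
non-heterogeneous without pCR n=51, HER2-heterogeneous without pCR n=14),
two spatially distinct pretreatment biopsies per patient plus residual
tumors for a no-pCR subset, and FISH sampling of 6 tumor areas x 75 cells
per patient.

FISH cohorts are clonal mixtures: an amplified clone with negative-binomial
*ERBB2* counts (mean 12, dispersion 8, truncated >= 6) and a non-amplified
clone with Poisson counts truncated to fail the amplification rule, so a
patient's designed amplified fraction f_true is realized exactly
(n_amplified = round(f_true x n_cells)) and the call-level error is zero by
construction; an optional untruncated "noisy" mode quantifies rule-level
misclassification separately from sampling error.  Treatment is modeled as
clone-specific cell survival.

Expression cohorts are negative-binomial counts over structured gene
blocks: an *ERBB2*-amplicon block whose expression scales with f_true, a
basal block elevated in the heterogeneous group, a treatment-shift
direction with per-patient magnitude theta (the ground truth for responder
recovery), an orthogonal direction used to plant QC outliers, and a null
background, with log-normal library-size variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fish import HetClass, classify_het, _amplified_mask

__all__ = [
    "GroupSpec",
    "FISHSimConfig",
    "ExprSimConfig",
    "gen_fish_cohort",
    "apply_treatment",
    "apply_treatment_cohort",
    "gen_expression_cohort",
    "gen_if_cells",
    "gen_allele_counts",
]

# Cohort-level hotspot-mutation planting rates used by the default
# expression cohort: fraction of patients PIK3CA-mutant, fraction of those
# at H1047, and fraction of patients ERBB2-mutant (all at V777).
PIK3CA_MUTANT_RATE = 0.135
PIK3CA_H1047_SHARE = 0.706
ERBB2_MUTANT_RATE = 0.032


@dataclass(frozen=True)
class GroupSpec:
    """One patient group: size, designed amplified-fraction range, labels."""

    name: str
    n_patients: int
    f_range: tuple[float, float]
    pcr: bool
    het: bool


DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("nonhet_pcr", 64, (0.60, 0.95), pcr=True, het=False),
    GroupSpec("nonhet_nopcr", 51, (0.55, 0.95), pcr=False, het=False),
    GroupSpec("het_nopcr", 14, (0.10, 0.45), pcr=False, het=True),
)


@dataclass
class FISHSimConfig:
    """Clonal-mixture FISH cohort configuration.

    Amplified clone: erbb2 ~ NegBin(mean mu_amp, dispersion k_amp)
    truncated >= 6; cep17 ~ Poisson(cep17_mean) truncated >= 1.
    Non-amplified clone: erbb2 ~ Poisson(mu_non) truncated (given the
    cell's cep17) to fail the amplification rule unless ``noisy_non_amp``.
    Treatment: each cell survives independently with its clone's survival
    probability d_amp / d_non.
    """

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    n_areas: int = 6
    cells_per_area: int = 75
    mu_amp: float = 12.0
    k_amp: float = 8.0
    mu_non: float = 2.2
    cep17_mean: float = 2.0
    d_amp: float = 0.55
    d_non: float = 0.80
    noisy_non_amp: bool = False

    def validate(self) -> None:
        if self.n_areas < 1 or self.cells_per_area < 1:
            raise ValueError("areas and cells per area must be >= 1")
        for p in (self.d_amp, self.d_non):
            if not 0.0 <= p <= 1.0:
                raise ValueError("survival probabilities must be in [0, 1]")
        if min(self.mu_amp, self.k_amp, self.mu_non, self.cep17_mean) <= 0:
            raise ValueError("distribution parameters must be positive")
        for g in self.groups:
            lo, hi = g.f_range
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid f_range for group {g.name}")


def _truncated_poisson_ge1(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    out = rng.poisson(mean, size=n)
    while True:
        bad = out < 1
        if not bad.any():
            return out
        out[bad] = rng.poisson(mean, size=int(bad.sum()))


def _nb_trunc_ge(rng: np.random.Generator, mu: float, k: float, lo: int, n: int) -> np.ndarray:
    """Negative binomial (mean mu, dispersion k) truncated to >= lo."""
    p = k / (k + mu)
    out = rng.negative_binomial(k, p, size=n)
    while True:
        bad = out < lo
        if not bad.any():
            return out
        out[bad] = rng.negative_binomial(k, p, size=int(bad.sum()))


def _draw_amplified(rng: np.random.Generator, cfg: FISHSimConfig, n: int):
    erbb2 = _nb_trunc_ge(rng, cfg.mu_amp, cfg.k_amp, 6, n)
    cep17 = _truncated_poisson_ge1(rng, cfg.cep17_mean, n)
    return erbb2, cep17


def _draw_non_amplified(rng: np.random.Generator, cfg: FISHSimConfig, n: int):
    cep17 = _truncated_poisson_ge1(rng, cfg.cep17_mean, n)
    erbb2 = rng.poisson(cfg.mu_non, size=n)
    if not cfg.noisy_non_amp:
        while True:
            bad = _amplified_mask(erbb2, cep17)
            if not bad.any():
                break
            erbb2[bad] = rng.poisson(cfg.mu_non, size=int(bad.sum()))
    return erbb2, cep17


def gen_fish_cohort(
    cfg: FISHSimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a pretreatment FISH cohort.

    Returns (cells, truth).  ``cells`` has the per-cell input schema
    (patient_id, timepoint, area_id, erbb2, cep17, plus the hidden
    ``clone`` ground-truth column); ``truth`` is per patient with the
    designed fraction, group labels, and designed heterogeneity class.
    The amplified-cell count is exact: round(f_true x total cells),
    shuffled across areas (area assignment is provenance only).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_cells = cfg.n_areas * cfg.cells_per_area
    cell_rows = []
    truth_rows = []
    for g in cfg.groups:
        lo, hi = g.f_range
        f_true = rng.uniform(lo, hi, size=g.n_patients)
        for j in range(g.n_patients):
            pid = f"{g.name}_{j + 1:03d}"
            f = float(f_true[j])
            n_amp = int(round(f * n_cells))
            h_a, c_a = _draw_amplified(rng, cfg, n_amp)
            h_n, c_n = _draw_non_amplified(rng, cfg, n_cells - n_amp)
            erbb2 = np.concatenate([h_a, h_n])
            cep17 = np.concatenate([c_a, c_n])
            clone = np.array(["amp"] * n_amp + ["non"] * (n_cells - n_amp))
            order = rng.permutation(n_cells)
            area = np.repeat(np.arange(1, cfg.n_areas + 1), cfg.cells_per_area)
            cell_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "timepoint": "pre",
                        "area_id": [f"A{a}" for a in area],
                        "erbb2": erbb2[order],
                        "cep17": cep17[order],
                        "clone": clone[order],
                    }
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "group": g.name,
                    "pcr": g.pcr,
                    "het": g.het,
                    "f_true": f,
                    "n_cells": n_cells,
                    "designed_class": classify_het(n_amp / n_cells).value,
                    "mu_amp": cfg.mu_amp,
                    "k_amp": cfg.k_amp,
                    "mu_non": cfg.mu_non,
                    "seed": seed,
                }
            )
    cells = pd.concat(cell_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return cells, truth


def apply_treatment(
    cells: pd.DataFrame,
    d_amp: float,
    d_non: float,
    seed: int,
) -> pd.DataFrame:
    """Posttreatment sample(s): clone-wise independent cell survival.

    Amplified cells (by the per-cell FISH rule, so no ground-truth column is
    needed) survive with probability ``d_amp``, others with ``d_non``,
    independently.  If no cell of a patient survives, survival is redrawn
    (up to 100 times, then one uniformly chosen cell is retained) so every
    posttreatment sample keeps at least one cell.  Timepoint is set to
    'post'.
    """
    for p in (d_amp, d_non):
        if not 0.0 <= p <= 1.0:
            raise ValueError("survival probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for pid, grp in cells.groupby("patient_id", sort=True):
        amp = _amplified_mask(grp["erbb2"].values, grp["cep17"].values)
        p_surv = np.where(amp, d_amp, d_non)
        keep = rng.random(len(grp)) < p_surv
        tries = 0
        while not keep.any() and tries < 100:
            keep = rng.random(len(grp)) < p_surv
            tries += 1
        if not keep.any():  # degenerate policy (both survivals ~ 0)
            keep = np.zeros(len(grp), dtype=bool)
            keep[rng.integers(len(grp))] = True
        post = grp.loc[keep].copy()
        post["timepoint"] = "post"
        out.append(post)
    return pd.concat(out, ignore_index=True)


def apply_treatment_cohort(
    cells: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: FISHSimConfig,
    seed: int,
    residual_fraction_of_nopcr: float = 1.0,
) -> pd.DataFrame:
    """Residual-tumor FISH samples for (a subset of) no-pCR patients."""
    rng = np.random.default_rng(seed)
    nopcr = truth.loc[~truth["pcr"].astype(bool), "patient_id"]
    n_resid = int(round(len(nopcr) * residual_fraction_of_nopcr))
    chosen = set(rng.choice(nopcr.values, size=n_resid, replace=False))
    subset = cells[cells["patient_id"].isin(chosen)]
    return apply_treatment(subset, cfg.d_amp, cfg.d_non, seed=int(rng.integers(2**31)))


@dataclass
class ExprSimConfig:
    """Structured negative-binomial expression cohort configuration.

    Gene-block sizes must sum to at most ``n_genes``; the remainder is null
    background.  ``theta_range`` is the per-patient treatment-shift
    magnitude (log2 units along the fixed unit shift direction) for strong
    responders; heterogeneous-group patients draw from
    ``theta_range_het`` (minimal treatment-induced change).  Outliers are
    displaced along a direction orthogonal to the treatment shift by
    ``outlier_magnitude`` log2 units, sized to trip the 5-SD PC2 rule.
    """

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    n_genes: int = 2000
    n_amplicon: int = 40
    n_basal: int = 40
    n_shift: int = 100
    n_outlier_dir: int = 100
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.2
    amplicon_gain: float = 1.5       # log2 gain scaled by f_true
    basal_gain: float = 1.0          # log2 gain in the heterogeneous group
    dispersion: float = 60.0         # NB size parameter
    sd_patient: float = 0.30         # per-gene patient random effect, log2
    sd_biopsy: float = 0.10          # per-gene biopsy noise, log2
    theta_range: tuple[float, float] = (6.0, 18.0)
    theta_range_het: tuple[float, float] = (1.0, 6.0)
    lib_mean: float = 2e6
    lib_log_sd: float = 0.25
    n_outliers: int = 2
    outlier_magnitude: float = 40.0
    two_biopsy_fraction: float = 0.877
    post_fraction_of_nopcr: float = 0.66

    def validate(self) -> None:
        blocks = self.n_amplicon + self.n_basal + self.n_shift + self.n_outlier_dir
        if blocks > self.n_genes:
            raise ValueError("gene blocks exceed n_genes")
        for sd in (self.base_log2_sd, self.sd_patient, self.sd_biopsy, self.lib_log_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.dispersion <= 0 or self.lib_mean <= 0:
            raise ValueError("dispersion and library mean must be positive")
        if not 0 <= self.two_biopsy_fraction <= 1:
            raise ValueError("two_biopsy_fraction must be in [0, 1]")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-8)
    p = k / (k + mean)
    return rng.negative_binomial(k, p)


def gen_expression_cohort(
    cfg: ExprSimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate counts, sample metadata, and per-patient ground truth.

    Returns (counts genes x samples, metadata indexed by sample id, truth).
    Paired pretreatment biopsies share the patient effect and differ by
    biopsy noise; the posttreatment sample is the patient mean shifted by
    theta along the fixed unit direction; planted outlier samples are
    displaced along an orthogonal direction.  Truth records theta, planted
    hotspot-mutation status, f_true, and outlier sample ids.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    g0 = 0
    amplicon = slice(g0, g0 + cfg.n_amplicon); g0 += cfg.n_amplicon
    basal = slice(g0, g0 + cfg.n_basal); g0 += cfg.n_basal
    shift_sl = slice(g0, g0 + cfg.n_shift); g0 += cfg.n_shift
    outlier_sl = slice(g0, g0 + cfg.n_outlier_dir)

    genes = np.array(
        [f"AMP{i+1}" for i in range(cfg.n_amplicon)]
        + [f"BAS{i+1}" for i in range(cfg.n_basal)]
        + [f"SHF{i+1}" for i in range(cfg.n_shift)]
        + [f"OUT{i+1}" for i in range(cfg.n_outlier_dir)]
        + [f"BKG{i+1}" for i in range(cfg.n_genes - g0 - cfg.n_outlier_dir)]
    )
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=cfg.n_genes)

    shift_dir = np.zeros(cfg.n_genes)
    shift_dir[shift_sl] = rng.choice([-1.0, 1.0], size=cfg.n_shift)
    shift_dir /= np.linalg.norm(shift_dir)
    out_dir = np.zeros(cfg.n_genes)
    out_dir[outlier_sl] = rng.choice([-1.0, 1.0], size=cfg.n_outlier_dir)
    out_dir /= np.linalg.norm(out_dir)

    # patients and designed per-patient parameters
    patients = []
    for g in cfg.groups:
        lo, hi = g.f_range
        for j in range(g.n_patients):
            pid = f"{g.name}_{j + 1:03d}"
            theta_rng = cfg.theta_range_het if g.het else cfg.theta_range
            patients.append(
                {
                    "patient_id": pid,
                    "group": g.name,
                    "pcr": g.pcr,
                    "het": g.het,
                    "f_true": float(rng.uniform(lo, hi)),
                    "theta": float(rng.uniform(*theta_rng)) if not g.pcr else 0.0,
                    "hr_status": "pos" if rng.random() < 0.687 else "neg",
                    "rcb_score": 0.0 if g.pcr else float(rng.uniform(1.0, 4.0)),
                    "age": float(np.round(rng.uniform(28, 75), 1)),
                    "two_biopsies": bool(rng.random() < cfg.two_biopsy_fraction),
                }
            )
    truth = pd.DataFrame(patients)

    # plant hotspot mutations at cohort rates (ground truth for the screen)
    n_pat = len(truth)
    pik_mut = rng.random(n_pat) < PIK3CA_MUTANT_RATE
    pik_codon = np.where(
        rng.random(n_pat) < PIK3CA_H1047_SHARE,
        "H1047",
        rng.choice(["E542", "E545", "N345", "C420"], size=n_pat),
    )
    erbb2_mut = rng.random(n_pat) < ERBB2_MUTANT_RATE
    truth["pik3ca_mutant"] = pik_mut
    truth["pik3ca_codon"] = np.where(pik_mut, pik_codon, "")
    truth["erbb2_mutant"] = erbb2_mut
    truth["erbb2_codon"] = np.where(erbb2_mut, "V777", "")

    # posttreatment availability: subset of no-pCR patients
    nopcr_idx = truth.index[~truth["pcr"].astype(bool)].values
    n_post = int(round(len(nopcr_idx) * cfg.post_fraction_of_nopcr))
    post_idx = set(rng.choice(nopcr_idx, size=n_post, replace=False))
    truth["has_post"] = [i in post_idx for i in truth.index]

    sample_cols = {}
    meta_rows = []

    def patient_log2_mean(row) -> np.ndarray:
        mu = base.copy()
        mu[amplicon] += cfg.amplicon_gain * row["f_true"]
        if row["het"]:
            mu[basal] += cfg.basal_gain
        return mu

    for i, row in truth.iterrows():
        pid = row["patient_id"]
        mu_pat = patient_log2_mean(row) + rng.normal(0, cfg.sd_patient, cfg.n_genes)
        n_bx = 2 if row["two_biopsies"] else 1
        for b in range(1, n_bx + 1):
            sid = f"{pid}_pre{b}"
            log2_mu = mu_pat + rng.normal(0, cfg.sd_biopsy, cfg.n_genes)
            sample_cols[sid] = log2_mu
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "timepoint": "pre",
                    "biopsy_index": str(b),
                    "pcr": row["pcr"],
                    "het": row["het"],
                    "hr_status": row["hr_status"],
                    "rcb_score": row["rcb_score"],
                    "age": row["age"],
                }
            )
        if row["has_post"]:
            sid = f"{pid}_post"
            log2_mu = (
                mu_pat
                + row["theta"] * shift_dir
                + rng.normal(0, cfg.sd_biopsy, cfg.n_genes)
            )
            sample_cols[sid] = log2_mu
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "timepoint": "post",
                    "biopsy_index": "surgical",
                    "pcr": row["pcr"],
                    "het": row["het"],
                    "hr_status": row["hr_status"],
                    "rcb_score": row["rcb_score"],
                    "age": row["age"],
                }
            )

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    sample_ids = list(metadata.index)

    # plant outliers among pretreatment samples, orthogonal displacement
    pre_ids = [s for s in sample_ids if metadata.loc[s, "timepoint"] == "pre"]
    n_out = min(cfg.n_outliers, len(pre_ids))
    outlier_ids = sorted(rng.choice(pre_ids, size=n_out, replace=False))
    for sid in outlier_ids:
        sample_cols[sid] = sample_cols[sid] + cfg.outlier_magnitude * out_dir

    # realize counts with log-normal library sizes
    lib_sizes = cfg.lib_mean * np.exp(rng.normal(0, cfg.lib_log_sd, len(sample_ids)))
    counts = np.empty((cfg.n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        abundance = np.exp2(sample_cols[sid])
        mean = abundance / abundance.sum() * lib_sizes[j]
        counts[:, j] = _nb_counts(rng, mean, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    truth["is_outlier_patient"] = truth["patient_id"].isin(
        {metadata.loc[s, "patient_id"] for s in outlier_ids}
    )
    truth.attrs["outlier_samples"] = list(outlier_ids)
    truth.attrs["seed"] = seed
    return counts_df, metadata, truth


def gen_if_cells(
    n: int,
    strength: float,
    seed: int,
    pi_her2: float = 0.5,
    log_sd: float = 0.5,
    delta: float = 2.0,
    base_log_mean: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-clone log-normal immunofluorescence intensities.

    Clone A is HER2-high/CK5-low, clone B the reverse; ``strength`` in
    [0, 1] scales the log-mean separation ``delta`` (0 collapses both
    clones onto one component, the null).  Returns (cells, truth) where
    truth carries the latent clone label per cell.
    """
    if n < 10:
        raise ValueError("need at least 10 cells")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    clone_a = rng.random(n) < pi_her2
    sep = strength * delta / 2.0
    her2_logmu = np.where(clone_a, base_log_mean + sep, base_log_mean - sep)
    ck5_logmu = np.where(clone_a, base_log_mean - sep, base_log_mean + sep)
    her2 = np.exp(rng.normal(her2_logmu, log_sd))
    ck5 = np.exp(rng.normal(ck5_logmu, log_sd))
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i + 1}" for i in range(n)],
            "tumor_id": "T1",
            "her2_intensity": her2,
            "ck5_intensity": ck5,
        }
    )
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "clone": np.where(clone_a, "her2hi_ck5lo", "her2lo_ck5hi"),
            "strength": strength,
            "seed": seed,
        }
    )
    return cells, truth


def gen_allele_counts(
    sites: "pd.DataFrame | None",
    planted: "dict[tuple[str, str], float] | None",
    n_samples: int,
    seed: int,
    mean_depth: float = 80.0,
    error_rate: float = 0.001,
    zero_depth: "set[tuple[str, str]] | None" = None,
    sample_ids: "list[str] | None" = None,
    patient_of: "dict[str, str] | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial allele counts at hotspot sites.

    ``sites``: DataFrame with gene/codon_label columns (defaults to the
    shipped registry).  ``planted`` maps (sample_id, "GENE:CODON") to the
    true variant allele fraction; unplanted site-samples draw alt counts at
    the sequencing error rate.  ``zero_depth`` site-samples get depth 0 to
    exercise the coverage-exclusion rule.  Depth ~ Poisson(mean_depth).
    """
    from .hotspot import DEFAULT_SITES

    rng = np.random.default_rng(seed)
    if sites is None:
        sites = pd.DataFrame(
            [{"gene": s.gene, "codon_label": s.codon_label} for s in DEFAULT_SITES]
        )
    planted = planted or {}
    zero_depth = zero_depth or set()
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    rows, truth_rows = [], []
    for sid in sample_ids:
        for site in sites.itertuples():
            key = (sid, f"{site.gene}:{site.codon_label}")
            depth = 0 if key in zero_depth else int(rng.poisson(mean_depth))
            vaf_true = planted.get(key, 0.0)
            p = vaf_true if vaf_true > 0 else error_rate
            alt = int(rng.binomial(depth, p)) if depth > 0 else 0
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": (patient_of or {}).get(sid, sid),
                    "gene": site.gene,
                    "codon_label": site.codon_label,
                    "depth": depth,
                    "alt_count": alt,
                }
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "gene": site.gene,
                    "codon_label": site.codon_label,
                    "true_vaf": vaf_true,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
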