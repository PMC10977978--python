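"""End-to-end cohort analysis orchestration.

A run consumes whichever inputs are present (per-cell FISH counts, a count
matrix with sample metadata, immunofluorescence intensities, allele
counts), executes the available stages in the study's analysis order —
heterogeneity profiling and pre/post transitions, transcriptomic
normalization + QC + distances + responder split, marker exclusivity,
hotspot screen — and writes one output directory.  Stages with missing
inputs are reported as skipped, never silently dropped; every output file
carries the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fish, hotspot, io, markers, rnaseq

__all__ = ["RunConfig", "StageFailure", "validate_inputs", "run_pipeline", "render_report"]

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE = 3


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters for a full run; None paths skip their stage."""

    out_dir: str
    fish_cells: "str | None" = None
    counts: "str | None" = None
    metadata: "str | None" = None
    if_cells: "str | None" = None
    allele_counts: "str | None" = None
    site_registry: "str | None" = None
    seed: int = 0
    equitability_denominator: str = "cells"
    copy_number_cap: "int | None" = None
    distance_space: str = "genes"
    distance_n_pcs: int = 10
    qc_component: str = "PC2"
    qc_n_sd: float = rnaseq.N_SD_QC
    per_tumor_median: bool = False
    min_depth: int = hotspot.MIN_DEPTH
    min_alt: int = hotspot.MIN_ALT
    min_vaf: float = hotspot.MIN_VAF

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise io.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_inputs(cfg: RunConfig) -> io.ValidationReport:
    """Schema-check every referenced input; collect hard errors and warnings."""
    report = io.ValidationReport()
    readers = {
        "fish_cells": io.read_fish_cells,
        "counts": io.read_counts_tsv,
        "metadata": io.read_sample_metadata,
        "if_cells": io.read_if_cells,
        "allele_counts": io.read_allele_counts,
    }
    any_input = False
    for attr, reader in readers.items():
        path = getattr(cfg, attr)
        if path is None:
            continue
        any_input = True
        if not Path(path).exists():
            report.errors.append(f"{attr}: path does not exist: {path}")
            continue
        try:
            reader(path)
        except io.ValidationError as e:
            report.errors.append(f"{attr}: {e}")
    if (cfg.counts is None) != (cfg.metadata is None):
        report.errors.append("counts and metadata must be provided together")
    if not any_input:
        report.errors.append("no inputs provided")
    if cfg.equitability_denominator not in {"species", "cells"}:
        report.errors.append("equitability_denominator must be 'species' or 'cells'")
    if cfg.distance_space not in {"genes", "pcs"}:
        report.errors.append("distance_space must be 'genes' or 'pcs'")
    return report


def _fish_stage(cfg: RunConfig, provenance: list[str], out: Path) -> dict:
    cells = io.read_fish_cells(cfg.fish_cells)
    profiles = fish.profiles_from_table(
        cells, denominator=cfg.equitability_denominator, cap=cfg.copy_number_cap
    )
    io.write_table(profiles, out / "fish_profiles.tsv", provenance)
    pre = profiles[profiles["timepoint"] == "pre"]
    post = profiles[profiles["timepoint"] == "post"]
    summary: dict = {
        "n_patients": int(profiles["patient_id"].nunique()),
        "pre_class_counts": pre["het_class"].value_counts().to_dict(),
        "post_class_counts": post["het_class"].value_counts().to_dict(),
    }
    if not pre.empty and not post.empty:
        def to_profiles(sub):
            samples = fish.samples_from_table(
                cells[cells["timepoint"] == sub]
            )
            return [
                fish.profile(s, denominator=cfg.equitability_denominator,
                             cap=cfg.copy_number_cap)
                for s in samples
            ]

        records, matrix, unmatched = fish.transitions(
            to_profiles("pre"), to_profiles("post")
        )
        rec_df = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "pre_class": r.pre_class.value,
                    "post_class": r.post_class.value,
                    "delta_equitability": r.delta_equitability,
                    "delta_fraction": r.delta_fraction,
                    "delta_aggregate_ratio": r.delta_aggregate_ratio,
                }
                for r in records
            ]
        )
        io.write_table(rec_df, out / "fish_transitions.tsv", provenance)
        io.write_table(matrix, out / "fish_transition_matrix.tsv", provenance, index=True)
        io.write_json(
            {"matrix": matrix.to_dict(), "unmatched": unmatched},
            out / "fish_transition_matrix.json",
        )
        summary["transition_matrix"] = matrix.to_dict()
        summary["unmatched"] = unmatched
        if records:
            summary["mean_delta_equitability"] = float(
                np.mean([r.delta_equitability for r in records])
            )
    return summary


def _rnaseq_stage(cfg: RunConfig, provenance: list[str], out: Path) -> dict:
    counts = io.read_counts_tsv(cfg.counts)
    metadata = io.read_sample_metadata(cfg.metadata)
    m = rnaseq.ExpressionMatrix(counts, metadata)
    m = rnaseq.filter_zero_genes(m)
    norm = rnaseq.log_cpm(m, rnaseq.tmm_factors(m))
    n_pcs = max(2, min(10, len(norm.samples) - 1, norm.values.shape[0]))
    scores, var_frac = rnaseq.pca_scores(norm, n_components=n_pcs)
    qc = rnaseq.pc2_outlier_filter(scores, component=cfg.qc_component, n_sd=cfg.qc_n_sd)
    io.write_json(
        {
            "excluded": qc.excluded.to_dict(orient="records"),
            "n_retained": len(qc.retained),
            "component": qc.component,
            "n_sd": qc.n_sd,
            "variance_fractions": list(map(float, var_frac)),
        },
        out / "qc_report.json",
    )
    # QC exclusion applies once, before all downstream analyses
    kept = rnaseq.ExpressionMatrix(m.counts[qc.retained], m.metadata.loc[qc.retained])
    kept = rnaseq.filter_zero_genes(kept)
    norm = rnaseq.log_cpm(kept, rnaseq.tmm_factors(kept))
    io.write_table(
        norm.values.rename_axis("gene"), out / "normalized_log2_tmm_cpm.tsv",
        provenance, index=True,
    )
    io.write_table(
        norm.tmm_factors.rename_axis("sample_id").reset_index(),
        out / "tmm_factors.tsv", provenance,
    )
    dist, missing = rnaseq.treatment_distances(
        norm, space=cfg.distance_space, n_pcs=cfg.distance_n_pcs
    )
    intra, single = rnaseq.intra_pair_distances(norm)
    summary: dict = {
        "n_samples_retained": len(qc.retained),
        "n_samples_excluded": len(qc.excluded),
        "n_pre_post_pairs": int(len(dist)),
        "patients_missing_timepoint": missing,
        "single_biopsy_patients": single,
    }
    if len(dist) >= 4:
        dist = rnaseq.responder_split(dist)
        summary["weak_threshold"] = dist.attrs["weak_threshold"]
        summary["n_weak"] = int((dist["responder"] == "WEAK").sum())
        summary["n_strong"] = int((dist["responder"] == "STRONG").sum())
    io.write_table(pd.concat([dist, intra], ignore_index=True),
                   out / "distances.tsv", provenance)
    if not dist.empty:
        summary["mean_pre_post_distance"] = float(dist["distance"].mean())
    if intra["distance"].notna().any():
        summary["mean_intra_pair_distance"] = float(intra["distance"].mean())
    return summary


def _markers_stage(cfg: RunConfig, provenance: list[str], out: Path) -> dict:
    cells = io.read_if_cells(cfg.if_cells)
    result = markers.exclusivity_analysis(cells, per_tumor_median=cfg.per_tumor_median)
    io.write_table(result.labels, out / "if_labels.tsv", provenance)
    payload = {
        "table": result.table.tolist(),
        "odds_ratio": result.odds_ratio,
        "p_value": result.p_value,
        "pearson_r": result.pearson_r,
        "pearson_p": result.pearson_p,
        "her2_median": result.her2_median,
        "ck5_median": result.ck5_median,
        "n_cells": int(result.table.sum()),
    }
    io.write_json(payload, out / "if_exclusivity.json")
    return payload


def _hotspot_stage(cfg: RunConfig, provenance: list[str], out: Path) -> dict:
    counts = io.read_allele_counts(cfg.allele_counts)
    registry = (
        hotspot.load_site_registry(cfg.site_registry)
        if cfg.site_registry
        else None
    )
    calls = hotspot.call_table(
        counts, registry, min_depth=cfg.min_depth, min_alt=cfg.min_alt,
        min_vaf=cfg.min_vaf,
    )
    io.write_table(calls, out / "hotspot_calls.tsv", provenance)
    summary = hotspot.cohort_summary(calls)
    io.write_json(summary, out / "hotspot_summary.json")
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages with available inputs; returns the summary report.

    Raises ValidationError on schema failure and StageFailure (naming the
    stage) on any stage error; outputs are written per stage, so a failed
    stage leaves earlier stages' files intact and is reported as such.
    """
    report = validate_inputs(cfg)
    report.raise_if_failed()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg.as_dict())
    provenance = [f"config_hash: {chash}", f"seed: {cfg.seed}"]
    stages = {
        "fish_het": (cfg.fish_cells is not None, _fish_stage),
        "transcriptome": (cfg.counts is not None, _rnaseq_stage),
        "marker_if": (cfg.if_cells is not None, _markers_stage),
        "hotspot": (cfg.allele_counts is not None, _hotspot_stage),
    }
    summary: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}, "skipped": []}
    for name, (enabled, fn) in stages.items():
        if not enabled:
            summary["skipped"].append(name)
            continue
        try:
            summary["stages"][name] = fn(cfg, provenance, out)
        except Exception as e:  # abort with stage name and cause
            raise StageFailure(name, e) from e
    io.write_json(summary, out / "run_summary.json")
    (out / "report.md").write_text(render_report(summary), encoding="utf-8")
    return summary


def render_report(summary: dict) -> str:
    """Human-readable cohort report from a run summary."""
    lines = [
        "# Cohort analysis report",
        "",
        f"- config hash: `{summary['config_hash']}`",
        f"- seed: {summary['seed']}",
        f"- skipped stages: {', '.join(summary['skipped']) or 'none'}",
        "",
    ]
    s = summary["stages"]
    if "fish_het" in s:
        f = s["fish_het"]
        lines += [
            "## ERBB2 FISH heterogeneity",
            f"- patients profiled: {f['n_patients']}",
            f"- pretreatment class counts: {f['pre_class_counts']}",
        ]
        if "transition_matrix" in f:
            lines.append(f"- posttreatment class counts: {f['post_class_counts']}")
            lines.append(
                f"- mean pre-to-post equitability change: "
                f"{f.get('mean_delta_equitability', float('nan')):.4f}"
            )
        lines.append("")
    if "transcriptome" in s:
        t = s["transcriptome"]
        lines += [
            "## Transcriptomic distances",
            f"- samples retained after QC: {t['n_samples_retained']} "
            f"(excluded: {t['n_samples_excluded']})",
            f"- pre-to-post pairs: {t['n_pre_post_pairs']}",
        ]
        if "n_weak" in t:
            lines.append(
                f"- responder split: {t['n_weak']} weak / {t['n_strong']} strong "
                f"(threshold {t['weak_threshold']:.4f})"
            )
        lines.append("")
    if "marker_if" in s:
        m = s["marker_if"]
        lines += [
            "## HER2/CK5 exclusivity",
            f"- cells: {m['n_cells']}; odds ratio: {m['odds_ratio']:.4g}; "
            f"Fisher p: {m['p_value']:.3g}; Pearson r: {m['pearson_r']:.3f}",
            "",
        ]
    if "hotspot" in s:
        lines.append("## Hotspot screen")
        for gene, g in s["hotspot"]["genes"].items():
            lines.append(
                f"- {gene}: {g['n_patients_mutant']}/{g['n_patients_covered']} "
                f"patients mutant ({100 * g['patient_mutant_fraction']:.1f}%)"
            )
        lines.append("")
    return "\n".join(lines)
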