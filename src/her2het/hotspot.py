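"""Hotspot-mutation screening from per-site allele counts.

Recurrent activating mutations in *PIK3CA* (e.g., E542K/E545K in the
helical domain, H1047R in the kinase domain) and *ERBB2* (L755, V777) are
established resistance markers to HER2-targeted therapy.  This module
screens tabulated allele counts (sample, site, depth, alternate-allele
count) against a configurable site registry with explicit evidence
thresholds, and summarizes cohort mutation frequencies with samples lacking
coverage excluded from denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
import yaml

__all__ = [
    "CallStatus",
    "HotspotSite",
    "VariantCall",
    "DEFAULT_SITES",
    "default_site_registry",
    "load_site_registry",
    "call_site",
    "call_table",
    "cohort_summary",
]

# Evidence thresholds (all configurable): minimum read depth for the site
# to count as covered, minimum alternate reads and minimum variant allele
# fraction to call a mutation.
MIN_DEPTH = 10
MIN_ALT = 3
MIN_VAF = 0.05


class CallStatus(str, Enum):
    MUTANT = "MUTANT"
    WILDTYPE = "WILDTYPE"
    NO_COVERAGE = "NO_COVERAGE"


@dataclass(frozen=True)
class HotspotSite:
    """One screened codon; exon labels are opaque registry text."""

    gene: str
    codon_label: str
    exon_label: str = ""
    position_key: str = ""

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.codon_label}"


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    site: HotspotSite
    status: CallStatus
    vaf: float  # NaN when depth < min_depth
    depth: int
    alt_count: int


DEFAULT_SITES: tuple[HotspotSite, ...] = (
    HotspotSite("PIK3CA", "N345", "5"),
    HotspotSite("PIK3CA", "C420", "8"),
    HotspotSite("PIK3CA", "E542", "10"),
    HotspotSite("PIK3CA", "E545", "10"),
    HotspotSite("PIK3CA", "H1047", "21"),
    HotspotSite("ERBB2", "L755", "22"),
    HotspotSite("ERBB2", "V777", "23"),
)


def default_site_registry() -> dict[str, HotspotSite]:
    return {s.key: s for s in DEFAULT_SITES}


def load_site_registry(path) -> dict[str, HotspotSite]:
    """Load a YAML site registry: list of {gene, codon_label, exon_label, position_key}."""
    with open(path, "r", encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    registry: dict[str, HotspotSite] = {}
    for e in entries:
        site = HotspotSite(
            gene=str(e["gene"]),
            codon_label=str(e["codon_label"]),
            exon_label=str(e.get("exon_label", "")),
            position_key=str(e.get("position_key", "")),
        )
        if site.key in registry:
            raise ValueError(f"duplicate site {site.key} in registry")
        registry[site.key] = site
    return registry


def call_site(
    sample_id: str,
    site: HotspotSite,
    depth: int,
    alt_count: int,
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT,
    min_vaf: float = MIN_VAF,
) -> VariantCall:
    """NO_COVERAGE below min_depth; MUTANT iff alt >= min_alt and VAF >= min_vaf."""
    if depth < 0 or alt_count < 0:
        raise ValueError("depth and alt_count must be non-negative")
    if alt_count > depth:
        raise ValueError(f"alt_count {alt_count} exceeds depth {depth}")
    if depth < min_depth:
        return VariantCall(sample_id, site, CallStatus.NO_COVERAGE, float("nan"), depth, alt_count)
    vaf = alt_count / depth
    status = (
        CallStatus.MUTANT
        if alt_count >= min_alt and vaf >= min_vaf
        else CallStatus.WILDTYPE
    )
    return VariantCall(sample_id, site, status, vaf, depth, alt_count)


def call_table(
    counts: pd.DataFrame,
    registry: "dict[str, HotspotSite] | None" = None,
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT,
    min_vaf: float = MIN_VAF,
) -> pd.DataFrame:
    """Call every row of an allele-count table.

    Expects columns sample_id, gene, codon_label, depth, alt_count and an
    optional patient_id column (defaults to sample_id) used for
    patient-level summaries.  Sites absent from the registry are an error —
    a screen against an unknown coordinate is meaningless.
    """
    registry = registry or default_site_registry()
    required = ["sample_id", "gene", "codon_label", "depth", "alt_count"]
    for col in required:
        if col not in counts.columns:
            raise ValueError(f"allele-count table missing column {col!r}")
    rows = []
    for r in counts.itertuples():
        key = f"{r.gene}:{r.codon_label}"
        site = registry.get(key)
        if site is None:
            raise ValueError(f"site {key} not in registry")
        call = call_site(
            str(r.sample_id), site, int(r.depth), int(r.alt_count),
            min_depth=min_depth, min_alt=min_alt, min_vaf=min_vaf,
        )
        rows.append(
            {
                "sample_id": call.sample_id,
                "patient_id": str(getattr(r, "patient_id", r.sample_id)),
                "gene": site.gene,
                "codon_label": site.codon_label,
                "exon_label": site.exon_label,
                "depth": call.depth,
                "alt_count": call.alt_count,
                "vaf": call.vaf,
                "status": call.status.value,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(calls: pd.DataFrame) -> dict:
    """Cohort mutation frequencies with coverage-aware denominators.

    Per gene, the sample denominator excludes samples with NO_COVERAGE at
    every site of that gene.  A patient is counted mutant in a gene if any
    of their biopsies is MUTANT at any site of the gene (any-biopsy rule);
    patients with both MUTANT and WILDTYPE calls at the same site across
    biopsies are flagged discordant.  The per-codon distribution is over
    mutant patients.
    """
    if calls.empty:
        raise ValueError("cohort_summary requires at least one call")
    out: dict = {"genes": {}, "n_samples": int(calls["sample_id"].nunique())}
    for gene, g in calls.groupby("gene"):
        covered = g[g["status"] != CallStatus.NO_COVERAGE.value]
        samples_covered = set(covered["sample_id"])
        mutant_rows = g[g["status"] == CallStatus.MUTANT.value]
        mutant_samples = set(mutant_rows["sample_id"])
        # patient-level: any biopsy mutant -> mutant
        patients_covered = set(covered["patient_id"])
        mutant_patients = set(mutant_rows["patient_id"])
        codon_dist: dict[str, float] = {}
        if mutant_patients:
            per_codon = (
                mutant_rows.drop_duplicates(["patient_id", "codon_label"])
                .groupby("codon_label")["patient_id"]
                .nunique()
            )
            codon_dist = {
                codon: int(npat) / len(mutant_patients)
                for codon, npat in per_codon.items()
            }
        # discordance: same patient, same codon, both MUTANT and WILDTYPE
        discordant = []
        for (pid, codon), sub in g.groupby(["patient_id", "codon_label"]):
            st = set(sub["status"])
            if CallStatus.MUTANT.value in st and CallStatus.WILDTYPE.value in st:
                discordant.append({"patient_id": str(pid), "codon_label": str(codon)})
        out["genes"][gene] = {
            "n_samples_covered": len(samples_covered),
            "n_samples_mutant": len(mutant_samples),
            "sample_mutant_fraction": (
                len(mutant_samples) / len(samples_covered) if samples_covered else 0.0
            ),
            "n_patients_covered": len(patients_covered),
            "n_patients_mutant": len(mutant_patients),
            "patient_mutant_fraction": (
                len(mutant_patients) / len(patients_covered) if patients_covered else 0.0
            ),
            "codon_distribution": codon_dist,
            "discordant_patients": discordant,
        }
    return out
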