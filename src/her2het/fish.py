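"""Single-cell *ERBB2* FISH amplification-heterogeneity quantification.

Each tumor cell carries two integer signal counts from dual-probe FISH: the
*ERBB2* gene probe and the chromosome-17 centromere control probe (CEP17).
A cell is called amplified under the ASCO/CAP-style disjunction
(*ERBB2*/CEP17 ratio >= 2 or *ERBB2* copies >= 6).  Pooling all counted
cells of a patient at one timepoint, each distinct (erbb2, cep17) tuple is
treated as a copy-number "species"; the Shannon index over species
frequencies and its normalization (Pielou evenness, the Shannon
equitability index) quantify cellular copy-number diversity.  A tumor is
HER2-heterogeneous (HET) when the amplified-cell fraction lies strictly
between 5% and 50%.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Timepoint",
    "HetClass",
    "RatioGroup",
    "CellFISHCount",
    "FISHSample",
    "SpeciesDistribution",
    "HeterogeneityProfile",
    "TransitionRecord",
    "call_amplified",
    "fraction_amplified",
    "species_distribution",
    "shannon_index",
    "equitability",
    "aggregate_ratio",
    "classify_het",
    "ratio_group",
    "profile",
    "profiles_from_table",
    "transitions",
]

# HET definition: amplified cells represent more than 5% but less than 50%
# of the population (strict inequalities; ties fall to the adjacent class).
HET_LOWER = 0.05
HET_UPPER = 0.50
# Per-cell amplification rule.
AMP_RATIO_THRESHOLD = 2.0
AMP_COPY_THRESHOLD = 6
# Tumor-level ratio grouping (inclusive lower bound).
HIGH_RATIO_THRESHOLD = 6.0


class Timepoint(str, Enum):
    """Biopsy timepoint relative to neoadjuvant treatment."""

    PRE = "pre"
    POST = "post"

    @classmethod
    def parse(cls, value: "str | Timepoint") -> "Timepoint":
        if isinstance(value, Timepoint):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"timepoint must be 'pre' or 'post', got {value!r}"
            ) from None


class HetClass(str, Enum):
    """Tumor-level amplification-heterogeneity class."""

    HET = "HET"                  # 5% < amplified fraction < 50%
    NON_HET_AMP = "NON_HET_AMP"  # amplified fraction >= 50%
    NON_AMP = "NON_AMP"          # amplified fraction <= 5%


class RatioGroup(str, Enum):
    """Tumor-level ERBB2/CEP17 ratio group (high copy-number gain >= 6)."""

    HIGH = "HIGH"
    LOW = "LOW"


@dataclass(frozen=True)
class CellFISHCount:
    """One tumor cell's FISH signal counts with provenance."""

    patient_id: str
    timepoint: Timepoint
    area_id: str
    erbb2: int
    cep17: int

    def __post_init__(self) -> None:
        if not str(self.patient_id):
            raise ValueError("patient_id must be non-empty")
        if not str(self.area_id):
            raise ValueError("area_id must be non-empty")
        object.__setattr__(self, "timepoint", Timepoint.parse(self.timepoint))
        for name in ("erbb2", "cep17"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))


@dataclass(frozen=True)
class FISHSample:
    """All counted cells of one patient at one timepoint (areas pooled)."""

    patient_id: str
    timepoint: Timepoint
    cells: tuple[CellFISHCount, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoint", Timepoint.parse(self.timepoint))
        cells = tuple(self.cells)
        if not cells:
            raise ValueError("FISHSample requires at least one cell")
        for c in cells:
            if c.patient_id != self.patient_id or c.timepoint != self.timepoint:
                raise ValueError(
                    "all cells must share the sample's patient_id and timepoint"
                )
        object.__setattr__(self, "cells", cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_areas(self) -> int:
        return len({c.area_id for c in self.cells})

    @classmethod
    def from_counts(
        cls,
        patient_id: str,
        timepoint: "str | Timepoint",
        pairs: Iterable[tuple[int, int]],
        area_id: str = "1",
    ) -> "FISHSample":
        """Build a sample from bare (erbb2, cep17) pairs in a single area."""
        tp = Timepoint.parse(timepoint)
        cells = tuple(
            CellFISHCount(patient_id, tp, area_id, int(h), int(c)) for h, c in pairs
        )
        return cls(patient_id, tp, cells)


@dataclass(frozen=True)
class SpeciesDistribution:
    """Multiset tally of (erbb2, cep17) copy-number species."""

    species: Mapping[tuple[int, int], int]
    total_cells: int
    n_species: int
    frequencies: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("distribution requires at least one species")
        if any(n <= 0 for n in self.species.values()):
            raise ValueError("species counts must be positive")
        if abs(sum(self.frequencies.values()) - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")


@dataclass(frozen=True)
class HeterogeneityProfile:
    """Per patient-timepoint heterogeneity summary."""

    patient_id: str
    timepoint: Timepoint
    fraction_amplified: float
    shannon_h: float
    equitability: float        # primary, per the selected denominator
    equitability_cells: float  # H / ln(total cells)
    equitability_species: float  # H / ln(n_species), Pielou evenness
    aggregate_ratio: float
    mean_erbb2: float
    n_cells: int
    n_species: int
    het_class: HetClass
    ratio_group: RatioGroup


@dataclass(frozen=True)
class TransitionRecord:
    """Pre-to-post change of one patient's heterogeneity profile."""

    patient_id: str
    pre_class: HetClass
    post_class: HetClass
    delta_equitability: float
    delta_fraction: float
    delta_aggregate_ratio: float


def call_amplified(cell: "CellFISHCount | tuple[int, int]") -> bool:
    """Per-cell amplification call: ERBB2/CEP17 >= 2 or ERBB2 copies >= 6.

    With CEP17 = 0 the ratio is undefined and the call rests on the
    copy-number arm of the disjunction alone.
    """
    if isinstance(cell, CellFISHCount):
        h, c = cell.erbb2, cell.cep17
    else:
        h, c = cell
    if h >= AMP_COPY_THRESHOLD:
        return True
    return c > 0 and h / c >= AMP_RATIO_THRESHOLD


def _amplified_mask(erbb2: np.ndarray, cep17: np.ndarray) -> np.ndarray:
    """Vectorized amplification rule on aligned count arrays."""
    erbb2 = np.asarray(erbb2, dtype=float)
    cep17 = np.asarray(cep17, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_ok = np.where(cep17 > 0, erbb2 / np.where(cep17 > 0, cep17, 1) >= AMP_RATIO_THRESHOLD, False)
    return ratio_ok | (erbb2 >= AMP_COPY_THRESHOLD)


def _apply_cap(pairs: Sequence[tuple[int, int]], cap: "int | None") -> list[tuple[int, int]]:
    if cap is None:
        return list(pairs)
    if cap < 1:
        raise ValueError("cap must be a positive integer")
    return [(min(h, cap), min(c, cap)) for h, c in pairs]


def fraction_amplified(sample: FISHSample) -> float:
    """Fraction of amplified cells out of the entire counted population."""
    n_amp = sum(call_amplified(c) for c in sample.cells)
    return n_amp / sample.n_cells


def species_distribution(sample: FISHSample, cap: "int | None" = None) -> SpeciesDistribution:
    """Tally (erbb2, cep17) tuples; ``cap`` optionally bins saturated counts."""
    pairs = _apply_cap([(c.erbb2, c.cep17) for c in sample.cells], cap)
    tally = Counter(pairs)
    total = sum(tally.values())
    freqs = {sp: n / total for sp, n in tally.items()}
    return SpeciesDistribution(
        species=dict(tally), total_cells=total, n_species=len(tally), frequencies=freqs
    )


def shannon_index(dist: SpeciesDistribution) -> float:
    """Shannon index H = -sum p ln p over species frequencies, in nats."""
    h = -sum(p * math.log(p) for p in dist.frequencies.values() if p > 0)
    return max(h, 0.0)  # clamp -0.0 from a single species


def equitability(dist: SpeciesDistribution, denominator: str = "cells") -> float:
    """Shannon equitability E = H / ln(denominator).

    ``denominator="cells"`` (default) normalizes by ln(total cells), the
    self-consistent reading of defining each species frequency as its cell
    count over the total cell count and dividing H by the log of that same
    total; ``denominator="species"`` is Pielou evenness, H/ln(S), the
    classical normalization by the maximum entropy at the observed species
    richness.  Both are bounded in [0, 1] (H <= ln S <= ln N).  A
    single-species distribution has no diversity and returns 0 by
    convention (the 0/0 limit from near-degenerate distributions).
    """
    h = shannon_index(dist)
    if denominator == "species":
        denom = math.log(dist.n_species) if dist.n_species > 1 else 0.0
    elif denominator == "cells":
        denom = math.log(dist.total_cells) if dist.total_cells > 1 else 0.0
    else:
        raise ValueError("denominator must be 'species' or 'cells'")
    if denom == 0.0:
        return 0.0
    # all-distinct cells give H = ln N up to rounding; keep E in [0, 1]
    return min(h / denom, 1.0)


def aggregate_ratio(sample: FISHSample) -> float:
    """Tumor-level ERBB2/CEP17: ratio of summed signals over all cells."""
    sum_h = sum(c.erbb2 for c in sample.cells)
    sum_c = sum(c.cep17 for c in sample.cells)
    if sum_c == 0:
        raise ValueError(
            "total CEP17 signal is zero: control channel uninterpretable"
        )
    return sum_h / sum_c


def classify_het(fraction: float) -> HetClass:
    """HET iff 5% < amplified fraction < 50% (strict); ties to the neighbor."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction <= HET_LOWER:
        return HetClass.NON_AMP
    if fraction >= HET_UPPER:
        return HetClass.NON_HET_AMP
    return HetClass.HET


def ratio_group(agg_ratio: float) -> RatioGroup:
    """HIGH iff the tumor-level ERBB2/CEP17 ratio is >= 6 (inclusive)."""
    return RatioGroup.HIGH if agg_ratio >= HIGH_RATIO_THRESHOLD else RatioGroup.LOW


def profile(
    sample: FISHSample,
    denominator: str = "cells",
    cap: "int | None" = None,
) -> HeterogeneityProfile:
    """Full heterogeneity profile of one patient-timepoint sample.

    Cells from all areas are pooled; area identifiers are provenance only.
    Both equitability normalizations are reported, with ``denominator``
    selecting which one fills the primary ``equitability`` field.
    """
    dist = species_distribution(sample, cap=cap)
    frac = fraction_amplified(sample)
    agg = aggregate_ratio(sample)
    e_species = equitability(dist, "species")
    e_cells = equitability(dist, "cells")
    primary = equitability(dist, denominator)
    return HeterogeneityProfile(
        patient_id=sample.patient_id,
        timepoint=sample.timepoint,
        fraction_amplified=frac,
        shannon_h=shannon_index(dist),
        equitability=primary,
        equitability_cells=e_cells,
        equitability_species=e_species,
        aggregate_ratio=agg,
        mean_erbb2=float(np.mean([c.erbb2 for c in sample.cells])),
        n_cells=sample.n_cells,
        n_species=dist.n_species,
        het_class=classify_het(frac),
        ratio_group=ratio_group(agg),
    )


def samples_from_table(cells: pd.DataFrame) -> list[FISHSample]:
    """Group a validated per-cell table into FISHSample objects.

    Expects columns patient_id, timepoint, area_id, erbb2, cep17.
    """
    out: list[FISHSample] = []
    for (pid, tp), grp in cells.groupby(["patient_id", "timepoint"], sort=True):
        tp = Timepoint.parse(tp)
        cs = tuple(
            CellFISHCount(str(pid), tp, str(r.area_id), int(r.erbb2), int(r.cep17))
            for r in grp.itertuples()
        )
        out.append(FISHSample(str(pid), tp, cs))
    return out


def profiles_from_table(
    cells: pd.DataFrame,
    denominator: str = "cells",
    cap: "int | None" = None,
) -> pd.DataFrame:
    """Per patient-timepoint profile table from a per-cell count table."""
    rows = []
    for s in samples_from_table(cells):
        p = profile(s, denominator=denominator, cap=cap)
        rows.append(
            {
                "patient_id": p.patient_id,
                "timepoint": p.timepoint.value,
                "n_cells": p.n_cells,
                "n_areas": s.n_areas,
                "n_species": p.n_species,
                "fraction_amplified": p.fraction_amplified,
                "shannon_h": p.shannon_h,
                "equitability": p.equitability,
                "equitability_cells": p.equitability_cells,
                "equitability_species": p.equitability_species,
                "aggregate_ratio": p.aggregate_ratio,
                "mean_erbb2": p.mean_erbb2,
                "het_class": p.het_class.value,
                "ratio_group": p.ratio_group.value,
            }
        )
    return pd.DataFrame(rows)


_CLASS_ORDER = [HetClass.HET, HetClass.NON_HET_AMP, HetClass.NON_AMP]


def transitions(
    pre_profiles: Iterable[HeterogeneityProfile],
    post_profiles: Iterable[HeterogeneityProfile],
) -> tuple[list[TransitionRecord], pd.DataFrame, dict[str, list[str]]]:
    """Pair pre and post profiles by patient and tabulate class shifts.

    Returns (records, 3x3 transition-count matrix with pre classes as rows
    and post classes as columns, unmatched report).  Patients present at
    only one timepoint are reported under ``unmatched``, never dropped
    silently; duplicate patient-timepoint profiles are an error.
    """
    def index(profiles: Iterable[HeterogeneityProfile], tp: Timepoint):
        d: dict[str, HeterogeneityProfile] = {}
        for p in profiles:
            if p.patient_id in d:
                raise ValueError(
                    f"duplicate {tp.value} profile for patient {p.patient_id!r}"
                )
            d[p.patient_id] = p
        return d

    pre = index(pre_profiles, Timepoint.PRE)
    post = index(post_profiles, Timepoint.POST)
    shared = sorted(set(pre) & set(post))
    unmatched = {
        "pre_only": sorted(set(pre) - set(post)),
        "post_only": sorted(set(post) - set(pre)),
    }
    labels = [c.value for c in _CLASS_ORDER]
    matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    records: list[TransitionRecord] = []
    for pid in shared:
        a, b = pre[pid], post[pid]
        records.append(
            TransitionRecord(
                patient_id=pid,
                pre_class=a.het_class,
                post_class=b.het_class,
                delta_equitability=b.equitability - a.equitability,
                delta_fraction=b.fraction_amplified - a.fraction_amplified,
                delta_aggregate_ratio=b.aggregate_ratio - a.aggregate_ratio,
            )
        )
        matrix.loc[a.het_class.value, b.het_class.value] += 1
    return records, matrix, unmatched
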