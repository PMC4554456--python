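"""Per-sample phenotypes and binary indicator tables.

Each sample's compositional profile is reduced to categorical variables:

* per-phylogroup abundance category — dominant (>50% of the population),
  intermediate (10-50%), minor (<10% but detected), absent (undetected);
* CFU class — high (>1e7 CFU/g), intermediate ([1e6, 1e7]), low (<1e6);
* diversity class — high iff all four phylogroups are detected;
* enterocolitype — E1..E5, a deterministic rule combining the dominant
  phylogroup with the host domain (see :func:`assign_enterocolitype`).

Phenotypes and host metadata are then expanded into fixed-order 0/1
indicator tables, the input to correspondence analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hosts import ANIMAL_SPECIES, DIETS, HostProfile
from .quantify import PHYLOGROUPS, PhylogroupProfile
from .virulence import B2_SUBGROUPS, VF_GENES, ORIGIN_GROUPS, StrainVFProfile, vf_score

DOMINANT_THRESHOLD = 0.50
INTERMEDIATE_LOW = 0.10
EXCLUSIVITY_THRESHOLD = 0.90
CFU_LOW_BOUND = 1e6
CFU_HIGH_BOUND = 1e7

CATEGORIES = ("dominant", "intermediate", "minor", "absent")

#: fixed column order of the 32-variable animal table.  The phylogroup
#: block lists exactly the 14 named category variables (there is no
#: "minor A" or "absent A" column: A is quantified by subtraction with a
#: 15% detection limit, so those states carry no indicator and such a
#: sample contributes no 1 in the A block).
ANIMAL32_COLUMNS: tuple[str, ...] = (
    "DA", "DB1", "DB2", "DD",
    "IA", "IB1", "IB2", "ID",
    "MB1", "MB2", "MD",
    "AB1", "AB2", "AD",
    "cfu_high", "cfu_intermediate", "cfu_low",
    "diversity_high", "diversity_low",
    *ANIMAL_SPECIES,
    "wild", "domesticated",
    *DIETS,
)

#: fixed column order of the 33-variable B2-strain table: origin group
#: (3), B2 subgroup incl. unassigned (9), the 20 virulence genes, and the
#: high-virulence flag (score >= 9).
STRAIN33_COLUMNS: tuple[str, ...] = (
    *ORIGIN_GROUPS,
    *(f"SG_{sg}" for sg in B2_SUBGROUPS),
    "SG_unassigned",
    *VF_GENES,
    "vf_score_ge9",
)

_CATEGORY_COLUMN = {
    ("A", "dominant"): "DA", ("A", "intermediate"): "IA",
    ("B1", "dominant"): "DB1", ("B1", "intermediate"): "IB1",
    ("B1", "minor"): "MB1", ("B1", "absent"): "AB1",
    ("B2", "dominant"): "DB2", ("B2", "intermediate"): "IB2",
    ("B2", "minor"): "MB2", ("B2", "absent"): "AB2",
    ("D", "dominant"): "DD", ("D", "intermediate"): "ID",
    ("D", "minor"): "MD", ("D", "absent"): "AD",
}


@dataclass(frozen=True)
class SamplePhenotype:
    """Categorical description of one sample with detectable E. coli."""

    sample_id: str
    category: dict[str, str]  # phylogroup -> abundance category
    cfu_class: str  # high | intermediate | low
    diversity_class: str  # high | low
    n_groups_detected: int
    enterocolitype: str  # E1..E5 | unassigned

    def __post_init__(self) -> None:
        dominant = [g for g, c in self.category.items() if c == "dominant"]
        if len(dominant) > 1:
            raise ValueError(
                f"sample {self.sample_id!r}: more than one dominant "
                f"phylogroup: {dominant}"
            )
        if not 0 <= self.n_groups_detected <= 4:
            raise ValueError("n_groups_detected must be in 0..4")


@dataclass(frozen=True)
class IndicatorTable:
    """n x p 0/1 matrix with row and column labels."""

    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValueError("values shape does not match labels")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError("duplicate column labels")
        if values.shape[0] and (values.sum(axis=1) == 0).any():
            empty = [
                self.row_labels[i]
                for i in np.flatnonzero(values.sum(axis=1) == 0)
            ]
            raise ValueError(f"all-zero indicator row(s): {empty}")
        object.__setattr__(self, "values", values.astype(np.int8))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.row_labels),
            columns=list(self.column_labels),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IndicatorTable":
        return cls(
            row_labels=tuple(str(i) for i in frame.index),
            column_labels=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(),
        )


def categorize_phylogroup(
    proportion: float,
    detected: bool,
    *,
    dominant_threshold: float = DOMINANT_THRESHOLD,
    intermediate_low: float = INTERMEDIATE_LOW,
) -> str:
    """Abundance category of one phylogroup in one sample.

    Undetected phylogroups are "absent" regardless of the numeric value.
    Boundaries: dominant strictly >50%; intermediate closed [10%, 50%];
    minor <10% (and detected).
    """
    if not math.isfinite(proportion) or not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion!r}")
    if not detected:
        return "absent"
    if proportion > dominant_threshold:
        return "dominant"
    if proportion >= intermediate_low:
        return "intermediate"
    return "minor"


def classify_cfu(
    total_cfu: float,
    *,
    low_bound: float = CFU_LOW_BOUND,
    high_bound: float = CFU_HIGH_BOUND,
) -> str:
    """CFU class: high (>1e7), intermediate ([1e6, 1e7]), low (<1e6)."""
    if not total_cfu > 0:
        raise ValueError(f"total_cfu must be > 0, got {total_cfu!r}")
    if total_cfu > high_bound:
        return "high"
    if total_cfu < low_bound:
        return "low"
    return "intermediate"


def assign_enterocolitype(
    profile: PhylogroupProfile,
    category: dict[str, str],
    host: HostProfile,
    exclusivity_threshold: float = EXCLUSIVITY_THRESHOLD,
) -> str:
    """Deterministic enterocolitype rule.

    Humans: B2 above the exclusivity threshold (>90%) or B2 dominant ->
    E4; A dominant -> E5.  Animals: B2 dominant -> E1; B1 dominant -> E2;
    A dominant -> E3.  Anything else (including dominant D) is
    "unassigned" — a valid outcome, not an error.
    """
    dominant = next((g for g, c in category.items() if c == "dominant"), None)
    if host.is_human:
        if profile.p_b2 > exclusivity_threshold or dominant == "B2":
            return "E4"
        if dominant == "A":
            return "E5"
        return "unassigned"
    if dominant == "B2":
        return "E1"
    if dominant == "B1":
        return "E2"
    if dominant == "A":
        return "E3"
    return "unassigned"


def build_phenotype(
    profile: PhylogroupProfile,
    total_cfu: float,
    host: HostProfile,
    *,
    dominant_threshold: float = DOMINANT_THRESHOLD,
    intermediate_low: float = INTERMEDIATE_LOW,
    exclusivity_threshold: float = EXCLUSIVITY_THRESHOLD,
    cfu_low_bound: float = CFU_LOW_BOUND,
    cfu_high_bound: float = CFU_HIGH_BOUND,
) -> SamplePhenotype:
    """Derive the full categorical phenotype of one sample.

    Requires a profile with detection flags applied and detectable
    *E. coli* (samples without *E. coli* have no composition phenotype).
    """
    if profile.detected is None:
        raise ValueError(
            f"sample {profile.sample_id!r}: apply_detection_thresholds first"
        )
    if not profile.ecoli_present:
        raise ValueError(
            f"sample {profile.sample_id!r}: no E. coli detected; "
            "no phenotype defined"
        )
    category = {
        g: categorize_phylogroup(
            profile.proportion(g),
            profile.detected[g],
            dominant_threshold=dominant_threshold,
            intermediate_low=intermediate_low,
        )
        for g in PHYLOGROUPS
    }
    n_detected = sum(bool(profile.detected[g]) for g in PHYLOGROUPS)
    return SamplePhenotype(
        sample_id=profile.sample_id,
        category=category,
        cfu_class=classify_cfu(
            total_cfu, low_bound=cfu_low_bound, high_bound=cfu_high_bound
        ),
        diversity_class="high" if n_detected == 4 else "low",
        n_groups_detected=n_detected,
        enterocolitype=assign_enterocolitype(
            profile, category, host, exclusivity_threshold
        ),
    )


def _encode_animal_row(phenotype: SamplePhenotype, host: HostProfile) -> dict[str, int]:
    if host.is_human:
        raise ValueError(
            f"sample {phenotype.sample_id!r}: the 32-variable table covers "
            "animal hosts only"
        )
    row = dict.fromkeys(ANIMAL32_COLUMNS, 0)
    for group, cat in phenotype.category.items():
        column = _CATEGORY_COLUMN.get((group, cat))
        if column is not None:  # minor/absent A has no indicator column
            row[column] = 1
    row[f"cfu_{phenotype.cfu_class}"] = 1
    row[f"diversity_{phenotype.diversity_class}"] = 1
    row[host.species] = 1
    row[host.habitat] = 1
    row[host.diet] = 1
    return row


def _encode_strain_row(strain: StrainVFProfile) -> dict[str, int]:
    row = dict.fromkeys(STRAIN33_COLUMNS, 0)
    row[strain.origin_group] = 1
    subgroup = strain.b2_subgroup or "unassigned"
    row[f"SG_{subgroup}"] = 1
    for gene in VF_GENES:
        row[gene] = strain.genes[gene]
    row["vf_score_ge9"] = int(vf_score(strain) >= 9)
    return row


def drop_empty_columns(
    table: IndicatorTable,
) -> tuple[IndicatorTable, tuple[str, ...]]:
    """Remove all-zero columns (unobserved categories) from a table.

    Categories that never occur in a cohort have no chi-square profile
    and cannot enter a correspondence analysis; returns the pruned table
    and the dropped column labels.
    """
    keep = table.values.sum(axis=0) > 0
    dropped = tuple(
        c for c, k in zip(table.column_labels, keep) if not k
    )
    if not dropped:
        return table, ()
    pruned = IndicatorTable(
        row_labels=table.row_labels,
        column_labels=tuple(
            c for c, k in zip(table.column_labels, keep) if k
        ),
        values=table.values[:, keep],
    )
    return pruned, dropped


def build_indicator_table(samples, variable_set: str) -> IndicatorTable:
    """Expand phenotypes or strain profiles into a fixed-order 0/1 table.

    ``variable_set`` selects the coding: ``"animal32"`` expects
    ``(SamplePhenotype, HostProfile)`` pairs and yields the 32 animal
    variables; ``"strain33"`` expects :class:`StrainVFProfile` objects
    and yields the 33 strain variables.  Column order is fixed
    (:data:`ANIMAL32_COLUMNS` / :data:`STRAIN33_COLUMNS`) so tables are
    byte-reproducible.
    """
    if variable_set not in ("animal32", "strain33"):
        raise ValueError(
            f"variable_set must be 'animal32' or 'strain33', got {variable_set!r}"
        )
    samples = list(samples)
    if not samples:
        raise ValueError("cannot build an indicator table from zero samples")
    if variable_set == "animal32":
        columns = ANIMAL32_COLUMNS
        rows = [_encode_animal_row(ph, host) for ph, host in samples]
        labels = tuple(ph.sample_id for ph, _ in samples)
    else:
        columns = STRAIN33_COLUMNS
        rows = [_encode_strain_row(s) for s in samples]
        labels = tuple(s.strain_id for s in samples)
    values = np.array([[r[c] for c in columns] for r in rows], dtype=np.int8)
    return IndicatorTable(row_labels=labels, column_labels=columns, values=values)
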