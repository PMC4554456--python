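"""Virulence-factor scoring and group comparison of B2 strains.

B2 commensal strains are assayed for 20 extraintestinal virulence genes
(adhesins, iron-capture systems, protectins, toxins).  The virulence score
of a strain is the number of genes present out of the 20.  Strains are
grouped by origin: human strains whose B2 population excludes all other
phylogroups ("human exclusive"), human strains co-occurring with other
phylogroups ("human non-exclusive"), and animal strains.

A published survey of 43 such strains (20 human-exclusive, 10 human
non-exclusive, 13 animal) reports per-gene prevalences as percentages;
:data:`REFERENCE_PREVALENCE_PCT` carries those values and
:func:`reconstruct_counts` inverts the percentage formatting back to
integer positives per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: the 20 assayed virulence genes, in fixed report order.  ``sfa_foc``
#: stands for the sfa/foc determinant (F1C fimbriae); ``aer`` for the
#: aerobactin synthesis locus.
VF_GENES: tuple[str, ...] = (
    "papC", "papGIII", "sfa_foc", "iha", "hra", "ibeA",
    "fyuA", "irp2", "iroN", "aer", "ireA",
    "kpsMTII", "neuC", "ompT", "traT",
    "hlyC", "cnf1", "usp", "sat", "clbQ",
)

ORIGIN_GROUPS = ("human_exclusive", "human_nonexclusive", "animal")

#: B2 subgroups assayed by allele-specific typing (sequence-type
#: complexes); subgroup VI is not part of the assayed panel.
B2_SUBGROUPS = ("I", "II", "III", "IV", "V", "VII", "VIII", "IX")

#: published per-group prevalences (%) of the 20 genes among B2 commensal
#: strains.  Group sizes in :data:`REFERENCE_GROUP_N`.
REFERENCE_PREVALENCE_PCT: dict[str, dict[str, float]] = {
    "human_exclusive": {
        "papC": 45, "papGIII": 15, "sfa_foc": 50, "iha": 15, "hra": 35,
        "ibeA": 40, "fyuA": 95, "irp2": 95, "iroN": 80, "aer": 40,
        "ireA": 20, "kpsMTII": 60, "neuC": 60, "ompT": 80, "traT": 50,
        "hlyC": 35, "cnf1": 30, "usp": 95, "sat": 20, "clbQ": 60,
    },
    "human_nonexclusive": {
        "papC": 40, "papGIII": 10, "sfa_foc": 10, "iha": 40, "hra": 10,
        "ibeA": 40, "fyuA": 90, "irp2": 90, "iroN": 60, "aer": 20,
        "ireA": 40, "kpsMTII": 70, "neuC": 50, "ompT": 90, "traT": 80,
        "hlyC": 20, "cnf1": 10, "usp": 100, "sat": 30, "clbQ": 20,
    },
    "animal": {
        "papC": 0, "papGIII": 0, "sfa_foc": 15.38, "iha": 0, "hra": 38.46,
        "ibeA": 46.15, "fyuA": 84.62, "irp2": 84.62, "iroN": 46.15,
        "aer": 7.69, "ireA": 30.77, "kpsMTII": 61.54, "neuC": 23.08,
        "ompT": 84.62, "traT": 46.15, "hlyC": 7.69, "cnf1": 0,
        "usp": 46.15, "sat": 0, "clbQ": 15.38,
    },
}

REFERENCE_GROUP_N = {"human_exclusive": 20, "human_nonexclusive": 10, "animal": 13}


@dataclass(frozen=True)
class StrainVFProfile:
    """One B2 strain: 20 binary virulence genes plus origin metadata."""

    strain_id: str
    origin_group: str
    genes: dict[str, int]
    b2_subgroup: str | None = None
    o_type: str | None = None
    colicin_phage: bool | None = None

    def __post_init__(self) -> None:
        if self.origin_group not in ORIGIN_GROUPS:
            raise ValueError(
                f"strain {self.strain_id!r}: origin_group must be one of "
                f"{ORIGIN_GROUPS}, got {self.origin_group!r}"
            )
        extra = sorted(set(self.genes) - set(VF_GENES))
        missing = sorted(set(VF_GENES) - set(self.genes))
        if extra or missing:
            raise ValueError(
                f"strain {self.strain_id!r}: gene set mismatch "
                f"(missing {missing}, unknown {extra})"
            )
        bad = {g: v for g, v in self.genes.items() if v not in (0, 1)}
        if bad:
            raise ValueError(
                f"strain {self.strain_id!r}: gene values must be 0/1, got {bad}"
            )
        if self.b2_subgroup is not None and self.b2_subgroup not in (
            *B2_SUBGROUPS, "unassigned"
        ):
            raise ValueError(
                f"strain {self.strain_id!r}: b2_subgroup must be one of "
                f"{B2_SUBGROUPS} or 'unassigned', got {self.b2_subgroup!r}"
            )


def vf_score(profile: StrainVFProfile) -> int:
    """Number of virulence factors present out of the 20 assayed."""
    return sum(profile.genes[g] for g in VF_GENES)


class ReconstructedCount(NamedTuple):
    count: int
    consistent: bool


def reconstruct_counts(prevalence_percent: float, n: int) -> ReconstructedCount:
    """Invert percentage formatting back to an integer positive count.

    Returns the nearest-integer count and a consistency flag: the flag is
    False when re-formatting the count (``round(100 * count / n, 2)``)
    does not reproduce the printed percentage, indicating a typo or a
    different denominator.  The count is returned either way.
    """
    if not 0 <= prevalence_percent <= 100:
        raise ValueError(f"prevalence_percent must be in [0, 100], got {prevalence_percent}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    count = int(round(prevalence_percent / 100.0 * n))
    consistent = round(100.0 * count / n, 2) == round(float(prevalence_percent), 2)
    return ReconstructedCount(count, consistent)


def reconstruct_panel(
    group: str,
    prevalence_pct: dict[str, float] | None = None,
    n: int | None = None,
    id_prefix: str | None = None,
) -> list[StrainVFProfile]:
    """Synthetic strain panel matching published per-gene marginals exactly.

    For each gene the reconstructed positive count is assigned to the
    first k strains of the panel.  Marginal prevalences (and hence the
    mean virulence score, which depends only on marginals) are exact; the
    per-strain joint gene structure is a synthetic convention, not data.
    """
    if prevalence_pct is None:
        prevalence_pct = REFERENCE_PREVALENCE_PCT[group]
    if n is None:
        n = REFERENCE_GROUP_N[group]
    prefix = id_prefix if id_prefix is not None else group
    counts = {g: reconstruct_counts(prevalence_pct[g], n).count for g in VF_GENES}
    return [
        StrainVFProfile(
            strain_id=f"{prefix}_{i:03d}",
            origin_group=group,
            genes={g: int(i < counts[g]) for g in VF_GENES},
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class PrevalenceTable:
    """Per-gene, per-group prevalence summary with score statistics.

    ``positive_counts`` and ``prevalence`` are genes x groups frames;
    ``group_n``, ``mean_score`` and ``sd_score`` are per-group series.
    ``sd_score`` uses the n-1 denominator (NaN for singleton groups).
    The identity ``mean_score == prevalence.sum(axis=0)`` holds exactly.
    """

    positive_counts: pd.DataFrame
    prevalence: pd.DataFrame
    group_n: pd.Series
    mean_score: pd.Series
    sd_score: pd.Series


def group_prevalence(strains: Sequence[StrainVFProfile]) -> PrevalenceTable:
    """Tabulate per-gene prevalence and score statistics by origin group."""
    if not strains:
        raise ValueError("group_prevalence needs at least one strain")
    groups = [g for g in ORIGIN_GROUPS if any(s.origin_group == g for s in strains)]
    gene_matrix = pd.DataFrame(
        [[s.genes[g] for g in VF_GENES] for s in strains],
        columns=list(VF_GENES),
        index=[s.strain_id for s in strains],
    )
    origin = pd.Series([s.origin_group for s in strains], index=gene_matrix.index)
    scores = gene_matrix.sum(axis=1)

    positive = pd.DataFrame(
        {grp: gene_matrix.loc[origin == grp].sum(axis=0) for grp in groups}
    )
    n = pd.Series({grp: int((origin == grp).sum()) for grp in groups})
    return PrevalenceTable(
        positive_counts=positive,
        prevalence=positive / n,
        group_n=n,
        mean_score=pd.Series({grp: scores[origin == grp].mean() for grp in groups}),
        sd_score=pd.Series({grp: scores[origin == grp].std(ddof=1) for grp in groups}),
    )


class PrevalenceComparison(NamedTuple):
    chi2_stat: float
    chi2_p: float
    exact_p: float


def compare_prevalence(
    group_a_counts: tuple[int, int],
    group_b_counts: tuple[int, int],
    continuity_correction: bool = True,
) -> PrevalenceComparison:
    """Compare one gene's prevalence between two groups (2x2 table).

    Returns both the chi-square test (with a continuity-correction
    toggle) and the exact hypergeometric (Fisher) two-sided p-value.
    The exact test is the recommended default at the small group sizes
    typical of strain panels.
    """
    (a_pos, a_n), (b_pos, b_n) = group_a_counts, group_b_counts
    for pos, n in (group_a_counts, group_b_counts):
        if n < 1:
            raise ValueError("each group needs n >= 1")
        if not 0 <= pos <= n:
            raise ValueError(f"positives must lie in [0, n], got {pos}/{n}")
    table = np.array([[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]])
    exact_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if (table.sum(axis=0) == 0).any():
        # a margin is empty (all positive or all negative): chi-square is
        # undefined; there is trivially no association
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(
            table, correction=continuity_correction
        )
    return PrevalenceComparison(float(chi2_stat), float(chi2_p), exact_p)


class ScoreComparison(NamedTuple):
    statistic: float
    p_value: float
    test: str


def compare_scores(groups: Sequence[Sequence[float]]) -> ScoreComparison:
    """Compare virulence scores across groups with rank tests.

    Two groups: two-sided Wilcoxon rank-sum (Mann-Whitney U, exact when
    sample sizes permit and there are no ties).  More than two groups:
    Kruskal-Wallis.  Fully tied data across all groups yields p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        name = "wilcoxon_rank_sum" if len(arrays) == 2 else "kruskal_wallis"
        return ScoreComparison(0.0, 1.0, name)
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return ScoreComparison(float(res.statistic), float(res.pvalue), "wilcoxon_rank_sum")
    res = stats.kruskal(*arrays)
    return ScoreComparison(float(res.statistic), float(res.pvalue), "kruskal_wallis")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in
    reports, which mirror the uncorrected per-gene convention)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
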