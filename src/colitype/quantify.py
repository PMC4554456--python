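"""qPCR quantification of E. coli phylogroup proportions.

The measurement design: a 16S rDNA assay yields the total *E. coli* count
per gram of feces, and allele-specific probes yield counts for phylogroups
B1 (TspE4.C2), B2 (chuA/yjaA+) and D (chuA/yjaA-).  Phylogroup A carries no
specific probe; its proportion is obtained by subtracting the B1, B2 and D
proportions from 1.  A *yjaA* probe counts the A1 subgroup together with B2,
so ``p_A1 = (yjaa - b2) / total`` and ``p_A0 = p_A - p_A1``.

Detection limits are compositional: probe-based phylogroups are detectable
down to 0.1% of the total population, while A (obtained by subtraction) is
only trusted above 15%.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

PHYLOGROUPS = ("A", "B1", "B2", "D")

#: subtraction-based detection limit for phylogroup A (fraction of total)
SUBTRACTION_LOD_FRACTION = 0.15
#: probe-based detection limit for B1/B2/D (fraction of total)
PROBE_LOD_FRACTION = 0.001


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model for the qPCR assay.

    Parameters
    ----------
    log10_measurement_sd
        Standard deviation of the multiplicative measurement error in
        log10 space (per probe).  qPCR error is approximately constant on
        the CT (log) scale, hence the log-normal form.  The default of
        0.03 log10 corresponds to a replicate CT spread of about 0.1
        cycles.
    probe_lod_fraction
        Limit of detection of the phylogroup-specific probes, as a
        fraction of the measured total population (default 0.1%).
    subtraction_lod_fraction
        Limit of detection of phylogroup A, which is quantified by
        subtraction and therefore much less sensitive (default 15%).
    """

    log10_measurement_sd: float = 0.03
    probe_lod_fraction: float = PROBE_LOD_FRACTION
    subtraction_lod_fraction: float = SUBTRACTION_LOD_FRACTION

    def __post_init__(self) -> None:
        if self.log10_measurement_sd < 0:
            raise ValueError("log10_measurement_sd must be >= 0")
        if not 0 <= self.probe_lod_fraction < self.subtraction_lod_fraction < 1:
            raise ValueError(
                "need 0 <= probe_lod_fraction < subtraction_lod_fraction < 1, got "
                f"{self.probe_lod_fraction} and {self.subtraction_lod_fraction}"
            )


@dataclass(frozen=True)
class QPCRCounts:
    """Per-sample absolute abundances (CFU/g) from the qPCR assay."""

    sample_id: str
    total_cfu: float
    b1_cfu: float
    b2_cfu: float
    d_cfu: float
    yjaa_cfu: float

    def __post_init__(self) -> None:
        for name in ("total_cfu", "b1_cfu", "b2_cfu", "d_cfu", "yjaa_cfu"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} must be a finite "
                    f"non-negative number, got {value!r}"
                )
        if self.total_cfu == 0 and any(
            getattr(self, n) > 0 for n in ("b1_cfu", "b2_cfu", "d_cfu", "yjaa_cfu")
        ):
            raise ValueError(
                f"sample {self.sample_id!r}: zero total count with nonzero "
                "probe counts is inconsistent"
            )


@dataclass(frozen=True)
class PhylogroupProfile:
    """Compositional profile of one sample.

    Proportions are fractions of the total *E. coli* population.  When no
    *E. coli* was detected (``ecoli_present`` is False) the proportions are
    NaN and the sample is excluded from composition analyses.  ``detected``
    is filled by :func:`apply_detection_thresholds` and is None before.
    """

    sample_id: str
    p_a: float
    p_a1: float
    p_a0: float
    p_b1: float
    p_b2: float
    p_d: float
    ecoli_present: bool = True
    detected: Mapping[str, bool] | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def proportion(self, group: str) -> float:
        return {"A": self.p_a, "B1": self.p_b1, "B2": self.p_b2, "D": self.p_d}[group]


def ct_to_count(ct: float, slope: float, intercept: float) -> float:
    """Convert a cycle threshold to a count via a standard curve.

    The curve is ``ct = slope * log10(count) + intercept`` with a negative
    slope (more template -> earlier amplification), so
    ``count = 10 ** ((ct - intercept) / slope)``.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    if not math.isfinite(ct):
        raise ValueError(f"ct must be finite, got {ct}")
    return 10.0 ** ((ct - intercept) / slope)


def compute_proportions(counts: QPCRCounts) -> PhylogroupProfile:
    """Convert absolute qPCR counts to phylogroup proportions.

    ``p_A`` is the subtraction remainder ``1 - p_B1 - p_B2 - p_D``; it is
    clamped to 0 (with a recorded warning) when measurement noise pushes
    the probe sum above the 16S total.  Probe proportions exceeding 1 are
    capped at 1 with a warning.  Detection flags are *not* applied here;
    see :func:`apply_detection_thresholds`.
    """
    if counts.total_cfu == 0:
        nan = float("nan")
        return PhylogroupProfile(
            sample_id=counts.sample_id,
            p_a=nan, p_a1=nan, p_a0=nan, p_b1=nan, p_b2=nan, p_d=nan,
            ecoli_present=False,
            warnings=("no E. coli detected (zero total count)",),
        )

    warnings: list[str] = []
    total = counts.total_cfu
    props = {}
    for group, raw in (
        ("B1", counts.b1_cfu), ("B2", counts.b2_cfu), ("D", counts.d_cfu)
    ):
        p = raw / total
        if p > 1.0:
            warnings.append(
                f"{group} proportion {p:.4g} exceeds 1; capped at 1"
            )
            p = 1.0
        props[group] = p

    p_a = 1.0 - props["B1"] - props["B2"] - props["D"]
    if p_a < 0.0:
        warnings.append(
            f"subtraction gave negative A proportion {p_a:.4g}; clamped to 0"
        )
        p_a = 0.0

    p_a1 = (counts.yjaa_cfu - counts.b2_cfu) / total
    if p_a1 < 0.0:
        warnings.append(
            f"subtraction gave negative A1 proportion {p_a1:.4g}; clamped to 0"
        )
        p_a1 = 0.0
    if p_a1 > p_a:
        warnings.append(
            f"A1 proportion {p_a1:.4g} exceeds A proportion {p_a:.4g}; "
            "clamped to A"
        )
        p_a1 = p_a

    return PhylogroupProfile(
        sample_id=counts.sample_id,
        p_a=p_a,
        p_a1=p_a1,
        p_a0=p_a - p_a1,
        p_b1=props["B1"],
        p_b2=props["B2"],
        p_d=props["D"],
        ecoli_present=True,
        warnings=tuple(warnings),
    )


def apply_detection_thresholds(
    profile: PhylogroupProfile, noise: NoiseModel | None = None
) -> PhylogroupProfile:
    """Fill the per-phylogroup detection flags.

    Thresholds are inclusive (``>=``): they state the smallest detectable
    proportion.  A is detected at or above the subtraction limit (15% by
    default); B1, B2 and D at or above the probe limit (0.1%).  Undetected
    phylogroups keep their numeric proportion but are treated as "absent"
    by downstream categorisation.
    """
    if noise is None:
        noise = NoiseModel()
    if not profile.ecoli_present:
        detected = {g: False for g in PHYLOGROUPS}
    else:
        detected = {
            "A": profile.p_a >= noise.subtraction_lod_fraction,
            "B1": profile.p_b1 >= noise.probe_lod_fraction,
            "B2": profile.p_b2 >= noise.probe_lod_fraction,
            "D": profile.p_d >= noise.probe_lod_fraction,
        }
    return dataclasses.replace(profile, detected=detected)
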