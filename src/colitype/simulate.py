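"""Synthetic cohorts and strain panels.

The generator emulates the statistical structure the downstream analysis
assumes: each host carries a latent *E. coli* community whose phylogroup
composition is Dirichlet-distributed around an enterocolitype template,
whose total load is log-normal (parameters on the log10 CFU/g scale), and
which is observed through a qPCR assay with multiplicative log-normal
measurement error and compositional limits of detection.

Randomness uses one root seed with a named, order-independent substream
per sample (``SeedSequence([seed, template_index, sample_index])``), so
enlarging a cohort never perturbs previously generated samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hosts import SPECIES_TRAITS, HostProfile, host_for_species
from .quantify import NoiseModel, QPCRCounts
from .virulence import VF_GENES, StrainVFProfile

ENTEROCOLITYPES = ("E1", "E2", "E3", "E4", "E5")

#: default Dirichlet concentration for community compositions.  Chosen so
#: that a template's nominal dominant phylogroup stays dominant (>50%) in
#: essentially every draw; see docs/methods.md for the calibration.
DEFAULT_CONCENTRATION = 200.0


@dataclass(frozen=True)
class CommunityTemplate:
    """Generative template for one enterocolitype.

    ``composition_mean`` is the expected (A, B1, B2, D) proportion vector;
    per-sample compositions are drawn from
    ``Dirichlet(composition_concentration * composition_mean)`` (entries
    with mean exactly 0 are dropped from the Dirichlet and fixed at 0).
    Total load is ``10 ** Normal(log10_cfu_mean, log10_cfu_sd)`` CFU/g.
    ``host_species`` is the pool of species this community type occurs in;
    one is drawn uniformly per sample.
    """

    enterocolitype_label: str
    composition_mean: tuple[float, float, float, float]
    composition_concentration: float = DEFAULT_CONCENTRATION
    log10_cfu_mean: float = 7.0
    log10_cfu_sd: float = 0.5
    host_species: tuple[str, ...] = ("human",)
    a1_fraction_of_a: float = 0.5

    def __post_init__(self) -> None:
        mean = np.asarray(self.composition_mean, dtype=float)
        if mean.shape != (4,):
            raise ValueError("composition_mean must have 4 entries (A, B1, B2, D)")
        if np.any(mean < 0) or np.any(mean > 1):
            raise ValueError("composition_mean entries must lie in [0, 1]")
        if abs(mean.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition_mean must sum to 1 (got {mean.sum()!r})"
            )
        if self.composition_concentration <= 0:
            raise ValueError("composition_concentration must be > 0")
        if self.log10_cfu_sd <= 0:
            raise ValueError("log10_cfu_sd must be > 0")
        if not 0 <= self.a1_fraction_of_a <= 1:
            raise ValueError("a1_fraction_of_a must lie in [0, 1]")
        unknown = [s for s in self.host_species if s not in SPECIES_TRAITS]
        if unknown:
            raise ValueError(f"unknown host species: {unknown}")


@dataclass(frozen=True)
class TrueCommunity:
    """Latent state of one simulated sample (simulator plumbing)."""

    host_id: str
    true_proportions: tuple[float, float, float, float]  # (A, B1, B2, D)
    true_total_cfu: float
    true_a1_fraction_of_a: float = 0.5

    def __post_init__(self) -> None:
        props = np.asarray(self.true_proportions, dtype=float)
        if props.shape != (4,):
            raise ValueError("true_proportions must have 4 entries")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"true_proportions must sum to 1 (got {props.sum()!r})")
        if not self.true_total_cfu > 0:
            raise ValueError("true_total_cfu must be > 0")
        if not 0 <= self.true_a1_fraction_of_a <= 1:
            raise ValueError("true_a1_fraction_of_a must lie in [0, 1]")


def default_templates() -> list[CommunityTemplate]:
    """The five default enterocolitype templates.

    Compositions are configurable package defaults consistent with the
    qualitative cluster descriptions (dominant B2 / B1 / A; human exclusive
    B2; human dominant A) — they are NOT measured mixture values.  The
    log10 CFU/g parameters span the reported range from low wild-herbivore
    loads (5.49 +/- 1.45) to high human loads (7.89 +/- 0.52).
    """
    return [
        CommunityTemplate(
            "E1", (0.15, 0.05, 0.70, 0.10),
            log10_cfu_mean=5.5, log10_cfu_sd=1.0,
            host_species=("wild_rabbit", "deer"),
        ),
        CommunityTemplate(
            "E2", (0.15, 0.60, 0.05, 0.20),
            log10_cfu_mean=6.5, log10_cfu_sd=0.5,
            host_species=("domesticated_rabbit", "horse", "sheep", "cow"),
        ),
        CommunityTemplate(
            "E3", (0.60, 0.20, 0.05, 0.15),
            log10_cfu_mean=7.3, log10_cfu_sd=0.5,
            host_species=("boar", "pig", "chicken"),
        ),
        CommunityTemplate(
            "E4", (0.02, 0.01, 0.95, 0.02),
            log10_cfu_mean=7.9, log10_cfu_sd=0.52,
            host_species=("human",),
        ),
        CommunityTemplate(
            "E5", (0.60, 0.15, 0.10, 0.15),
            log10_cfu_mean=7.9, log10_cfu_sd=0.52,
            host_species=("human",),
        ),
    ]


def _substream(seed: int, *stream: int) -> np.random.Generator:
    """Named, order-independent RNG substream under one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def _draw_composition(
    template: CommunityTemplate, rng: np.random.Generator
) -> np.ndarray:
    mean = np.asarray(template.composition_mean, dtype=float)
    out = np.zeros(4)
    mask = mean > 0
    if mask.sum() == 1:
        out[mask] = 1.0  # degenerate: single nonzero component
        return out
    alpha = template.composition_concentration * mean[mask]
    out[mask] = rng.dirichlet(alpha)
    return out


def simulate_qpcr(
    community: TrueCommunity,
    noise: NoiseModel,
    seed: int | np.random.Generator,
) -> QPCRCounts:
    """Observe a latent community through the qPCR measurement model.

    Each probe count (16S total, B1, B2, D, yjaA) is the true count times
    an independent ``10 ** Normal(0, log10_measurement_sd)`` factor.  The
    yjaA probe targets the A1 subgroup and B2 together, so its true count
    is ``A1 + B2`` (the noise is then applied once, to the summed count).
    Probe counts below ``probe_lod_fraction`` of the *measured* total are
    censored to 0 — a detection limit, not an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _substream(seed)
    p_a, p_b1, p_b2, p_d = community.true_proportions
    total = community.true_total_cfu
    a1_true = community.true_a1_fraction_of_a * p_a * total
    true_counts = {
        "total": total,
        "b1": p_b1 * total,
        "b2": p_b2 * total,
        "d": p_d * total,
        "yjaa": a1_true + p_b2 * total,
    }
    sd = noise.log10_measurement_sd
    measured = {
        name: value * 10.0 ** rng.normal(0.0, sd)
        for name, value in true_counts.items()
    }
    lod = noise.probe_lod_fraction * measured["total"]
    for probe in ("b1", "b2", "d", "yjaa"):
        if measured[probe] < lod:
            measured[probe] = 0.0
    return QPCRCounts(
        sample_id=community.host_id,
        total_cfu=measured["total"],
        b1_cfu=measured["b1"],
        b2_cfu=measured["b2"],
        d_cfu=measured["d"],
        yjaa_cfu=measured["yjaa"],
    )


def simulate_cohort(
    templates: list[CommunityTemplate],
    n_per_template: int,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[tuple[HostProfile, TrueCommunity, QPCRCounts]]:
    """Generate a synthetic cohort: hosts, latent communities, qPCR reads.

    Deterministic given ``seed``; each sample uses its own named substream
    so results are independent of generation order and of
    ``n_per_template``.
    """
    if n_per_template < 1:
        raise ValueError("n_per_template must be >= 1")
    labels = [t.enterocolitype_label for t in templates]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate template labels: {labels}")
    if noise is None:
        noise = NoiseModel()

    cohort = []
    for ti, template in enumerate(templates):
        for si in range(n_per_template):
            rng = _substream(seed, ti, si)
            host_id = f"{template.enterocolitype_label}_{si:04d}"
            species = template.host_species[
                rng.integers(len(template.host_species))
            ]
            host = host_for_species(host_id, species)
            props = _draw_composition(template, rng)
            total = 10.0 ** rng.normal(template.log10_cfu_mean, template.log10_cfu_sd)
            community = TrueCommunity(
                host_id=host_id,
                true_proportions=tuple(props),
                true_total_cfu=total,
                true_a1_fraction_of_a=template.a1_fraction_of_a,
            )
            counts = simulate_qpcr(community, noise, rng)
            cohort.append((host, community, counts))
    return cohort


def simulate_strain_panel(
    group_label: str,
    n_strains: int,
    gene_prevalences: dict[str, float],
    seed: int = 0,
) -> list[StrainVFProfile]:
    """Draw a panel of B2 strains with independent Bernoulli gene carriage.

    ``gene_prevalences`` must name exactly the 20 assayed virulence genes
    (fractions in [0, 1]).  Deterministic given ``seed``; one substream per
    strain.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    unknown = sorted(set(gene_prevalences) - set(VF_GENES))
    if unknown:
        raise ValueError(f"unknown virulence gene name(s): {unknown}")
    missing = sorted(set(VF_GENES) - set(gene_prevalences))
    if missing:
        raise ValueError(f"missing virulence gene(s): {missing}")
    bad = {g: p for g, p in gene_prevalences.items() if not 0 <= p <= 1}
    if bad:
        raise ValueError(f"prevalences outside [0, 1]: {bad}")

    panel = []
    for i in range(n_strains):
        rng = _substream(seed, i)
        draws = rng.random(len(VF_GENES))
        genes = {
            gene: int(draws[j] < gene_prevalences[gene])
            for j, gene in enumerate(VF_GENES)
        }
        panel.append(
            StrainVFProfile(
                strain_id=f"{group_label}_{i:05d}",
                origin_group=group_label,
                genes=genes,
            )
        )
    return panel
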