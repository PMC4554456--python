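"""Host species, habitats and diets.

The cohort design covers nine animal species sampled in and around a
temperate forest/farm region, plus human subjects studied with the same
qPCR assay.  Habitat and diet are fully determined by the species, so a
single lookup table is the source of truth for both.
"""

from __future__ import annotations

from dataclasses import dataclass

#: species -> (habitat, diet).  Habitat is one of {"wild", "domesticated",
#: "human"}; diet is one of {"herbivorous", "omnivorous"}.
SPECIES_TRAITS: dict[str, tuple[str, str]] = {
    "horse": ("domesticated", "herbivorous"),
    "cow": ("domesticated", "herbivorous"),
    "sheep": ("domesticated", "herbivorous"),
    "pig": ("domesticated", "omnivorous"),
    "domesticated_rabbit": ("domesticated", "herbivorous"),
    "chicken": ("domesticated", "omnivorous"),
    "wild_rabbit": ("wild", "herbivorous"),
    "deer": ("wild", "herbivorous"),
    "boar": ("wild", "omnivorous"),
    "human": ("human", "omnivorous"),
}

#: the nine animal species, in the fixed order used for indicator columns
ANIMAL_SPECIES: tuple[str, ...] = (
    "horse",
    "cow",
    "sheep",
    "pig",
    "wild_rabbit",
    "domesticated_rabbit",
    "deer",
    "boar",
    "chicken",
)

HABITATS = ("wild", "domesticated", "human")
DIETS = ("herbivorous", "omnivorous")


@dataclass(frozen=True)
class HostProfile:
    """One sampled host individual.

    ``habitat`` and ``diet`` are stored explicitly (they travel through
    metadata files) but must agree with :data:`SPECIES_TRAITS`.
    """

    host_id: str
    species: str
    habitat: str
    diet: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES_TRAITS:
            raise ValueError(
                f"unknown species {self.species!r}; "
                f"known: {sorted(SPECIES_TRAITS)}"
            )
        habitat, diet = SPECIES_TRAITS[self.species]
        if self.habitat != habitat or self.diet != diet:
            raise ValueError(
                f"host {self.host_id!r}: species {self.species!r} implies "
                f"habitat={habitat!r}, diet={diet!r}, got "
                f"habitat={self.habitat!r}, diet={self.diet!r}"
            )

    @property
    def is_human(self) -> bool:
        return self.habitat == "human"


def host_for_species(host_id: str, species: str) -> HostProfile:
    """Build a :class:`HostProfile` with habitat/diet derived from species."""
    if species not in SPECIES_TRAITS:
        raise ValueError(
            f"unknown species {species!r}; known: {sorted(SPECIES_TRAITS)}"
        )
    habitat, diet = SPECIES_TRAITS[species]
    return HostProfile(host_id=host_id, species=species, habitat=habitat, diet=diet)
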