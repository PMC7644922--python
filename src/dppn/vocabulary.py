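"""The fixed 12-compartment subcellular location vocabulary.

Locations are matched literally by GO cellular-component ID; there is no
ontology traversal (a term outside the 12 is simply not a location we model).
"""

from __future__ import annotations

# Canonical display name -> GO CC identifier.
VOCABULARY: dict[str, str] = {
    "Cell cortex": "GO:0005938",
    "Cytosol": "GO:0005829",
    "Actin cytoskeleton": "GO:0015629",
    "Golgi apparatus": "GO:0005794",
    "Endoplasmic reticulum": "GO:0005783",
    "Nucleolus": "GO:0005730",
    "Peroxisome": "GO:0005777",
    "Mitochondrion": "GO:0005739",
    "Lysosome": "GO:0005764",
    "Centrosome": "GO:0005813",
    "Nucleus": "GO:0005634",
    "Plasma membrane": "GO:0005886",
}

LOCATIONS: tuple[str, ...] = tuple(VOCABULARY)

GO_TO_LOCATION: dict[str, str] = {go: name for name, go in VOCABULARY.items()}

# Short tokens used to build virtual locative protein IDs (<realID>::<token>).
LOCATION_TOKENS: dict[str, str] = {
    "Cell cortex": "cco",
    "Cytosol": "cyt",
    "Actin cytoskeleton": "act",
    "Golgi apparatus": "gol",
    "Endoplasmic reticulum": "er",
    "Nucleolus": "nuo",
    "Peroxisome": "per",
    "Mitochondrion": "mit",
    "Lysosome": "lys",
    "Centrosome": "cen",
    "Nucleus": "nuc",
    "Plasma membrane": "pm",
}

TOKEN_TO_LOCATION: dict[str, str] = {t: name for name, t in LOCATION_TOKENS.items()}

#: Index of each location in canonical vocabulary order.
LOCATION_INDEX: dict[str, int] = {name: i for i, name in enumerate(LOCATIONS)}


def sort_locations(locations) -> list[str]:
    """Return locations sorted in canonical vocabulary order."""
    return sorted(locations, key=LOCATION_INDEX.__getitem__)
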