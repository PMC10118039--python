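"""Controlled vocabularies: species, cultivation conditions, primary metabolites.

The primary-metabolite vocabulary holds exactly 28 entries — 20 amino acids,
5 organic acids and 3 sugars — each with its molecular carbon count, which is
what the carbon accounting needs to convert molar exudation rates into carbon
mass.
"""

from __future__ import annotations

SPECIES: tuple[str, ...] = ("mustard", "phacelia", "oat", "clover")
CONDITIONS: tuple[str, ...] = ("FIELD", "HYDRO")

#: metabolite -> (group, carbon atoms per molecule)
METABOLITE_VOCABULARY: dict[str, tuple[str, int]] = {
    # organic acids
    "Citrate": ("organic_acid", 6),
    "Isocitrate": ("organic_acid", 6),
    "Fumarate": ("organic_acid", 4),
    "Malate": ("organic_acid", 4),
    "Succinate": ("organic_acid", 4),
    # sugars
    "Glucose": ("sugar", 6),
    "Fructose": ("sugar", 6),
    "Sucrose": ("sugar", 12),
    # amino acids (GABA and ornithine included in the panel)
    "Ala": ("amino_acid", 3),
    "Arg": ("amino_acid", 6),
    "Asn": ("amino_acid", 4),
    "Asp": ("amino_acid", 4),
    "Gaba": ("amino_acid", 4),
    "Glu": ("amino_acid", 5),
    "Gln": ("amino_acid", 5),
    "Gly": ("amino_acid", 2),
    "His": ("amino_acid", 6),
    "Ile": ("amino_acid", 6),
    "Leu": ("amino_acid", 6),
    "Lys": ("amino_acid", 6),
    "Met": ("amino_acid", 5),
    "Orn": ("amino_acid", 5),
    "Phe": ("amino_acid", 9),
    "Pro": ("amino_acid", 5),
    "Ser": ("amino_acid", 3),
    "Thr": ("amino_acid", 4),
    "Tyr": ("amino_acid", 9),
    "Val": ("amino_acid", 5),
}

METABOLITE_GROUPS: tuple[str, ...] = ("amino_acid", "organic_acid", "sugar")

assert len(METABOLITE_VOCABULARY) == 28
assert sum(1 for g, _ in METABOLITE_VOCABULARY.values() if g == "amino_acid") == 20
assert sum(1 for g, _ in METABOLITE_VOCABULARY.values() if g == "organic_acid") == 5
assert sum(1 for g, _ in METABOLITE_VOCABULARY.values() if g == "sugar") == 3


def group_of(metabolite: str) -> str:
    """Metabolite group ('amino_acid', 'organic_acid' or 'sugar')."""
    try:
        return METABOLITE_VOCABULARY[metabolite][0]
    except KeyError:
        raise KeyError(
            f"unknown metabolite {metabolite!r}; known: {sorted(METABOLITE_VOCABULARY)}"
        ) from None


def carbon_atoms(metabolite: str) -> int:
    """Carbon atoms per molecule of a vocabulary metabolite."""
    try:
        return METABOLITE_VOCABULARY[metabolite][1]
    except KeyError:
        raise KeyError(
            f"unknown metabolite {metabolite!r}; known: {sorted(METABOLITE_VOCABULARY)}"
        ) from None


def group_key(species: str, condition: str) -> str:
    """Column label for a species x condition group, e.g. ``mustard|FIELD``."""
    return f"{species}|{condition}"


def split_group_key(key: str) -> tuple[str, str]:
    species, condition = key.split("|", 1)
    return species, condition
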