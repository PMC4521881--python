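"""Controlled vocabularies shared across the package.

Every categorical field in the input tables is validated against one of the
closed sets below; novel labels are rejected, never coerced silently.
"""

from __future__ import annotations

import re

GROUPS: tuple[str, ...] = (
    "cereals",
    "intertillage",
    "other field crops",
    "trees/shrubs",
    "weeds/grasses",
)

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")

#: Crude dry-matter fractions, expressed in mg per g dry matter.
DM_COMPONENTS: tuple[str, ...] = ("ash", "carbohydrates", "fat", "fibre", "protein")

#: Fatty acids as proportions of total identified FA. LA = linoleic acid
#: (C18:2 n-6), ALA = alpha-linolenic acid (C18:3 n-3).
FA_COMPONENTS: tuple[str, ...] = ("C14:0", "C16:0", "C16:1", "C18:0", "C18:1", "LA", "ALA")

SEXES: tuple[str, ...] = ("male", "female")
AGES: tuple[str, ...] = ("adult", "subadult")

#: Item schemes an electivity analysis can run over.
SCHEMES: tuple[str, ...] = ("taxa", "groups", "dm", "fa")

# Documented alias tables for free-text categorical input. Keys are compared
# after canonicalisation (casefold + whitespace collapse).
SEX_ALIASES: dict[str, str] = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}

AGE_ALIASES: dict[str, str] = {
    "ad": "adult",
    "adult": "adult",
    "sad": "subadult",
    "sub": "subadult",
    "subadult": "subadult",
    "juvenile": "subadult",
}

SEASON_ALIASES: dict[str, str] = {s: s for s in SEASONS}

_WS = re.compile(r"\s+")


def canonical(name: str) -> str:
    """Whitespace-collapsed, casefolded form used for all name matching."""
    return _WS.sub(" ", str(name).strip()).casefold()


def canonical_taxon(name: str) -> str:
    """Display form of a taxon name: whitespace collapsed, case preserved."""
    return _WS.sub(" ", str(name).strip())
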