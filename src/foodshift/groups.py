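"""Food-group taxonomy shared across the package.

Demand is tracked over ten *base* groups (six plant groups plus the four
animal-source-food groups).  Substitution scenarios introduce four
*alternative* groups (plant-based analogues and cultured meat/fish).
Adoption dynamics operate on three ASF *categories*: meat and fish share
one alternative market, dairy and eggs each have their own.
"""

from __future__ import annotations

PLANT_GROUPS: tuple[str, ...] = (
    "sugar",
    "oils_fats",
    "fruits_veg",
    "starchy_roots",
    "pulses",
    "cereals",
)

ASF_GROUPS: tuple[str, ...] = ("eggs", "dairy", "meat", "fish")

ALT_GROUPS: tuple[str, ...] = (
    "pb_eggs",
    "pb_dairy",
    "pb_meat_fish",
    "cultured_meat_fish",
)

BASE_GROUPS: tuple[str, ...] = PLANT_GROUPS + ASF_GROUPS
ALL_GROUPS: tuple[str, ...] = BASE_GROUPS + ALT_GROUPS

#: ASF adoption categories -> the base groups whose demand they displace.
CATEGORY_SOURCES: dict[str, tuple[str, ...]] = {
    "meat_fish": ("meat", "fish"),
    "dairy": ("dairy",),
    "eggs": ("eggs",),
}

#: ASF adoption categories -> (plant-based alternative, cultured alternative).
#: Only the meat/fish market has a cultured analogue.
CATEGORY_ALTERNATIVES: dict[str, tuple[str, str | None]] = {
    "meat_fish": ("pb_meat_fish", "cultured_meat_fish"),
    "dairy": ("pb_dairy", None),
    "eggs": ("pb_eggs", None),
}

ADOPTION_CATEGORIES: tuple[str, ...] = tuple(CATEGORY_SOURCES)
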