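"""The audited streetscape features and their coordinate eligibility.

Eight primitive pedestrian-environment features are audited per image;
"all crosswalks" is a derived composite (zebra + line) used only in
neighborhood summaries, never as a classifier target.
"""

from __future__ import annotations

import enum


class StreetFeature(str, enum.Enum):
    """Microscale streetscape features observable in street-level imagery."""

    SIDEWALK = "sidewalk"
    SIDEWALK_BUFFER = "sidewalk_buffer"
    CURB_CUT = "curb_cut"
    ZEBRA_CROSSWALK = "zebra_crosswalk"
    LINE_CROSSWALK = "line_crosswalk"
    WALK_SIGNAL = "walk_signal"
    BIKE_SYMBOL = "bike_symbol"
    STREETLIGHT = "streetlight"
    # derived composite, not a primitive classifier target
    ALL_CROSSWALKS = "all_crosswalks"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: The eight primitive (classifier-target) features, in canonical order.
PRIMITIVE_FEATURES: tuple[StreetFeature, ...] = (
    StreetFeature.SIDEWALK,
    StreetFeature.SIDEWALK_BUFFER,
    StreetFeature.CURB_CUT,
    StreetFeature.ZEBRA_CROSSWALK,
    StreetFeature.LINE_CROSSWALK,
    StreetFeature.WALK_SIGNAL,
    StreetFeature.BIKE_SYMBOL,
    StreetFeature.STREETLIGHT,
)

#: Features audited at intersection coordinates only (crossing furniture).
INTERSECTION_ONLY_FEATURES: frozenset[StreetFeature] = frozenset(
    {
        StreetFeature.ZEBRA_CROSSWALK,
        StreetFeature.LINE_CROSSWALK,
        StreetFeature.WALK_SIGNAL,
        StreetFeature.CURB_CUT,
    }
)

#: Features audited at every coordinate (present along segments too).
ALL_COORD_FEATURES: frozenset[StreetFeature] = frozenset(PRIMITIVE_FEATURES) - INTERSECTION_ONLY_FEATURES

#: Default eligibility map: feature -> allowed coordinate types.
DEFAULT_ELIGIBILITY: dict[StreetFeature, frozenset[str]] = {
    f: (frozenset({"intersection"}) if f in INTERSECTION_ONLY_FEATURES else frozenset({"intersection", "segment"}))
    for f in PRIMITIVE_FEATURES
}

#: Constituents of the total microscale score: 7 z-terms, with the two
#: crosswalk types entering once through the combined composite.
TOTAL_MICROSCALE_TERMS: tuple[StreetFeature, ...] = (
    StreetFeature.SIDEWALK,
    StreetFeature.SIDEWALK_BUFFER,
    StreetFeature.CURB_CUT,
    StreetFeature.ALL_CROSSWALKS,
    StreetFeature.WALK_SIGNAL,
    StreetFeature.BIKE_SYMBOL,
    StreetFeature.STREETLIGHT,
)

#: Land-use categories entering the land-use-mix entropy (fixed list of 7).
LAND_USE_CATEGORIES: tuple[str, ...] = (
    "residential",
    "retail",
    "recreational",
    "office",
    "civic",
    "food",
    "entertainment",
)
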