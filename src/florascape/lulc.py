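"""The land-use/land-cover (LULC) class scheme.

Nine classes describe the mosaic of the study landscape: six of them carry
their own vegetation-plot species pools; forest plantation and built-up are
floristically folded into agriculture (ruderal/exotic-dominated pools too
small to sample separately), and water bodies hold no vascular plants.
"""

from __future__ import annotations

# Canonical 9-class vocabulary.
LULC_CLASSES: tuple[str, ...] = (
    "agriculture",
    "agroforestry",
    "forest",
    "grassland",
    "regeneration",
    "savanna",
    "forest_plantation",
    "built_up",
    "water",
)

# Classes that carry a sampled species pool after the default merge.
ANALYSIS_CLASSES: tuple[str, ...] = (
    "agriculture",
    "agroforestry",
    "forest",
    "grassland",
    "regeneration",
    "savanna",
    "water",
)

# Natural-habitat classes: their pooled species define the "natural" group.
NATURAL_CLASSES: tuple[str, ...] = ("forest", "regeneration", "savanna")

# Default fold of the 9 mapped classes into the 7 analysis classes.
DEFAULT_CLASS_MERGE: dict[str, str] = {
    "forest_plantation": "agriculture",
    "built_up": "agriculture",
}

# Species groups reported throughout the pipeline.
GROUPS: tuple[str, ...] = ("all", "natural", "endemic", "redlist", "neophyte")

ALL_CLASSES_KEY = "all_classes"
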