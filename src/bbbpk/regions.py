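"""Canonical brain-region vocabulary for dissected terminal-sample studies.

The dissection scheme yields eleven named regions; ``"whole brain"`` is a
derived pseudo-region (all dissected regions except the olfactory bulb,
summed by weight and counts) and never appears in raw study files.
"""

from __future__ import annotations

CANONICAL_REGIONS: tuple[str, ...] = (
    "olfactory bulb",
    "striatum",
    "frontal cortex",
    "hypothalamus",
    "hippocampus",
    "thalamus",
    "parietal cortex",
    "occipital cortex",
    "cerebellum",
    "midbrain",
    "pons/medulla",
)

WHOLE_BRAIN = "whole brain"

#: Whole brain is computed from the dissected regions minus the olfactory bulb.
DEFAULT_WHOLE_BRAIN_EXCLUDE: tuple[str, ...] = ("olfactory bulb",)

#: Built-in spelling aliases.  Matching is exact after normalisation; no fuzzy
#: matching.  Users may extend this via an explicit alias mapping file.
BUILTIN_ALIASES: dict[str, str] = {
    "pons-medulla": "pons/medulla",
    "pons medulla": "pons/medulla",
}

GENOTYPES: tuple[str, ...] = ("E3", "E4")
SEXES: tuple[str, ...] = ("F", "M")

#: The four genotype x sex study groups.
GROUPS: tuple[tuple[str, str], ...] = (
    ("E3", "F"),
    ("E3", "M"),
    ("E4", "F"),
    ("E4", "M"),
)


def normalize_region(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map a region name onto the canonical vocabulary.

    Parameters
    ----------
    name:
        Region name as found in a study file; case- and whitespace-insensitive.
    aliases:
        Optional extra alias -> canonical-name mapping (applied after the
        built-in aliases).

    Raises
    ------
    ValueError
        If the name is not canonical and no alias covers it.
    """
    key = " ".join(name.strip().lower().split())
    key = BUILTIN_ALIASES.get(key, key)
    if aliases:
        key = aliases.get(key, key)
    if key == WHOLE_BRAIN:
        return WHOLE_BRAIN
    if key not in CANONICAL_REGIONS:
        raise ValueError(
            f"unknown brain region {name!r}; canonical regions are "
            f"{', '.join(CANONICAL_REGIONS)}"
        )
    return key
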