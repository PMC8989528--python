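"""Canned study designs: construct sets with their outcome profiles.

These encode the experimental conditions the simulator reproduces:

* ``txg_pair`` — the single-context experiment: one adenine control and one
  oxo-ϵA construct, both in the TXG context, mixed equimolar (the CRAB
  bypass setting).
* ``txg_lesion`` — the oxo-ϵA TXG construct alone (spectrum recovery).
* ``pool16`` — 32 constructs: adenine and oxo-ϵA in each of the 16
  trinucleotide contexts, equimolar.
* ``pool16_lesion`` — the 16 oxo-ϵA contexts alone.

Lesion constructs in GXC, GXG and GXT use the outcome preset with the ~2%
lesion->C leak; the other 13 contexts use the default pool preset.
"""

from __future__ import annotations

from .constructs import (ConstructLayout, enumerate_pool,
                         trinucleotide_contexts)
from .simulate import PRESETS, OutcomeProfile

__all__ = ["DESIGNS", "design_layouts", "profile_for"]

GXN_CONTEXTS = {"GXC", "GXG", "GXT"}
LESION_IDENTITY = "oxoeA"
CONTROL_IDENTITY = "A"

DESIGNS = ("txg_pair", "txg_lesion", "pool16", "pool16_lesion")


def profile_for(layout: ConstructLayout, pooled: bool) -> OutcomeProfile:
    """Outcome profile implied by a construct's identity and context."""
    if layout.base_identity == CONTROL_IDENTITY:
        return PRESETS["control_A"]
    if layout.base_identity != LESION_IDENTITY:
        raise ValueError(f"no outcome preset for identity "
                         f"{layout.base_identity!r}")
    if not pooled:
        if layout.context != "TXG":
            raise ValueError("the single-context presets are defined for "
                             "TXG only; use a pooled design")
        return PRESETS["oxoeA_TXG"]
    if layout.context in GXN_CONTEXTS:
        return PRESETS["oxoeA_pool_GXC_GXG_GXT"]
    return PRESETS["oxoeA_pool_default"]


def design_layouts(name: str
                   ) -> list[tuple[ConstructLayout, OutcomeProfile, float]]:
    """Equimolar genome mix (layout, profile, fraction) for a named design."""
    if name in ("txg_pair", "txg_lesion"):
        layouts = enumerate_pool(["TXG"],
                                 [CONTROL_IDENTITY, LESION_IDENTITY])
        if name == "txg_lesion":
            layouts = [l for l in layouts
                       if l.base_identity == LESION_IDENTITY]
        pooled = False
    elif name in ("pool16", "pool16_lesion"):
        identities = ([CONTROL_IDENTITY, LESION_IDENTITY]
                      if name == "pool16" else [LESION_IDENTITY])
        layouts = enumerate_pool(trinucleotide_contexts(), identities)
        pooled = True
    else:
        raise ValueError(f"unknown design {name!r}; available: {DESIGNS}")
    frac = 1.0 / len(layouts)
    return [(l, profile_for(l, pooled), frac) for l in layouts]
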