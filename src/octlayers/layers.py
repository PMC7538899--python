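"""Retinal sublayer naming and combination rules.

An 11-surface segmentation (internal limiting membrane to the outer
boundary of the RPE/Bruch's complex) yields 10 raw sublayers. The two
outer-segment sub-bands are merged into a single OS sublayer, giving the
9 analyzed layers. Two combined layers summarize the inner retina
(NFL through OPL) and outer retina (ONL through OS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Raw sublayers, in anatomical order inner -> outer, as delimited by the
#: 11 segmentation surfaces (surface k to surface k+1).
RAW_SUBLAYERS: tuple[str, ...] = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL", "EZ", "OS_a", "OS_b", "RPE",
)

#: The 9 analyzed layers after merging OS_a + OS_b into OS.
ANALYZED_LAYERS: tuple[str, ...] = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL", "EZ", "OS", "RPE",
)

#: Combined summary layers and their constituents (among analyzed layers).
COMBINED_LAYERS: dict[str, tuple[str, ...]] = {
    "inner_retina": ("NFL", "GCL", "IPL", "INL", "OPL"),
    "outer_retina": ("ONL", "EZ", "OS"),
}

#: All layers a cohort table may carry.
ALL_LAYERS: tuple[str, ...] = ANALYZED_LAYERS + tuple(COMBINED_LAYERS)

SUBFIELDS: tuple[str, ...] = ("center", "inner_ring", "outer_ring")

SOURCES: tuple[str, ...] = ("grader_a", "grader_b", "grader_avg", "uncorrected")

GROUPS: tuple[str, ...] = ("control", "stgd1")

EYES: tuple[str, ...] = ("OD", "OS")


@dataclass(frozen=True)
class LayerScheme:
    """Sublayer ordering and combination rules for an 11-surface segmentation."""

    raw_sublayers: tuple[str, ...] = RAW_SUBLAYERS
    os_merge: tuple[str, ...] = ("OS_a", "OS_b")
    combined: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(COMBINED_LAYERS)
    )

    @property
    def n_surfaces(self) -> int:
        return len(self.raw_sublayers) + 1

    @property
    def analyzed_layers(self) -> tuple[str, ...]:
        """Raw sublayers with the OS sub-bands merged into a single OS layer."""
        out: list[str] = []
        merged = False
        for name in self.raw_sublayers:
            if name in self.os_merge:
                if not merged:
                    out.append("OS")
                    merged = True
            else:
                out.append(name)
        return tuple(out)

    def __post_init__(self) -> None:
        if len(self.raw_sublayers) != 10:
            raise ValueError(
                f"expected 10 raw sublayers (11 surfaces), got {len(self.raw_sublayers)}"
            )
        missing = [s for s in self.os_merge if s not in self.raw_sublayers]
        if missing:
            raise ValueError(f"os_merge names not among raw sublayers: {missing}")
        analyzed = set(self.analyzed_layers)
        for name, parts in self.combined.items():
            bad = [p for p in parts if p not in analyzed]
            if bad:
                raise ValueError(f"combined layer {name!r} uses unknown layers {bad}")


DEFAULT_SCHEME = LayerScheme()
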