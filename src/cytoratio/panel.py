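"""The 21-cytokine serum panel and its pro-/anti-inflammatory partition.

Ratio features divide sums of pro-inflammatory cytokines by sums of
anti-inflammatory ones, so the panel carries the functional assignment of
each analyte alongside the canonical column order used everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CytokinePanel:
    """An ordered cytokine panel with a pro/anti-inflammatory assignment.

    Parameters
    ----------
    names
        All analytes, in canonical column order.
    pro
        Pro-inflammatory subset (ratio numerator candidates).
    anti
        Anti-inflammatory subset (ratio denominator candidates).

    Analytes in ``names`` but in neither functional list (e.g. MIP-3α, whose
    classification is debated) participate only as raw features, never in
    ratios.
    """

    names: tuple[str, ...]
    pro: tuple[str, ...] = field(default=())
    anti: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate cytokine names in panel")
        missing = (set(self.pro) | set(self.anti)) - set(self.names)
        if missing:
            raise ValueError(f"pro/anti members not in panel: {sorted(missing)}")
        if set(self.pro) & set(self.anti):
            raise ValueError("a cytokine cannot be both pro- and anti-inflammatory")

    @property
    def unassigned(self) -> tuple[str, ...]:
        assigned = set(self.pro) | set(self.anti)
        return tuple(n for n in self.names if n not in assigned)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def sort_members(self, members) -> tuple[str, ...]:
        """Return members in canonical order for ratio display.

        Members of a ratio side are ordered by their position in the pro-
        (respectively anti-) inflammatory list — the convention the study's
        nomograms print — falling back to overall panel position for
        unassigned analytes.
        """

        def key(name: str) -> tuple[int, int]:
            if name in self.pro:
                return (0, self.pro.index(name))
            if name in self.anti:
                return (1, self.anti.index(name))
            return (2, self.names.index(name))

        return tuple(sorted(members, key=key))


# Canonical panel: the high-sensitivity multiplex T-cell panel, 14
# pro-inflammatory and 6 anti-inflammatory cytokines; MIP-3α unassigned.
DEFAULT_PANEL = CytokinePanel(
    names=(
        "ITAC",
        "GM-CSF",
        "Fractalkine",
        "IFN-γ",
        "IL-10",
        "MIP-3α",
        "IL-12p70",
        "IL-13",
        "IL-17A",
        "IL-1β",
        "IL-2",
        "IL-21",
        "IL-4",
        "IL-23",
        "IL-5",
        "IL-6",
        "IL-7",
        "IL-8",
        "MIP-1α",
        "MIP-1β",
        "TNF-α",
    ),
    pro=(
        "ITAC",
        "GM-CSF",
        "Fractalkine",
        "IFN-γ",
        "IL-17A",
        "IL-1β",
        "IL-2",
        "IL-12p70",
        "IL-23",
        "IL-6",
        "IL-8",
        "MIP-1α",
        "MIP-1β",
        "TNF-α",
    ),
    anti=("IL-10", "IL-4", "IL-13", "IL-5", "IL-7", "IL-21"),
)
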