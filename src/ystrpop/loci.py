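"""Y-STR locus panels.

The 17-locus panel is the AmpFlSTR Yfiler marker set. For haplotype
diversity and dating work the panel is reduced to 15 loci: DYS385a/b are
dropped (the kit cannot assign alleles to the a vs b copy) and DYS389II
is re-expressed as DYS389II minus DYS389I (the II amplicon physically
contains the I repeat stretch, so the raw count double-counts it).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Locus:
    """A single Y-STR marker.

    Parameters
    ----------
    name : str
        Locus identifier, e.g. ``"DYS391"``.
    multicopy : bool
        True only for the DYS385a/b pair, whose two copies cannot be
        distinguished by the typing kit.
    mutation_rate : float or None
        Per-generation mutation rate (mutations/locus/generation), if known.
    """

    name: str
    multicopy: bool = False
    mutation_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if self.mutation_rate is not None and not (0.0 < self.mutation_rate < 0.05):
            raise ValueError(
                f"mutation rate for {self.name} must lie in (0, 0.05), "
                f"got {self.mutation_rate}"
            )


#: Yfiler 17-locus panel, in conventional reporting order.
YFILER_17: tuple[str, ...] = (
    "DYS19",
    "DYS385a",
    "DYS385b",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "GATA_H4",
)

#: Multicopy loci excluded from diversity/dating work.
MULTICOPY: tuple[str, ...] = ("DYS385a", "DYS385b")

#: The 15-locus panel used after normalization (DYS389II stored as II - I).
PANEL_15: tuple[str, ...] = tuple(l for l in YFILER_17 if l not in MULTICOPY)

# Repeat counts outside this range are treated as typos/parse errors.
MIN_REPEAT = 5
MAX_REPEAT = 50
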