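"""Item catalog for the 30-item PANSS instrument and its five symptom domains.

The default domain mapping is the empirically derived five-community
solution for schizophrenia-spectrum samples: Positive/Impaired Salience
(POS), Negative/Withdrawn-Disengaged (NEG), Impaired Cognition-Control
(COG), Impulsive-Hostile (HOS) and Distress (DST).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical column order: 7 positive, 7 negative, 16 general items.
PANSS_CODES: tuple[str, ...] = tuple(
    [f"P{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"G{i}" for i in range(1, 17)]
)

#: Label used for the suicidal-ideation node appended to item/cluster networks.
SUICIDE_NODE = "SUI"

DOMAINS: tuple[str, ...] = ("COG", "DST", "HOS", "NEG", "POS")

_DEFAULT_DOMAIN_OF: dict[str, str] = {
    # Positive / impaired salience
    "P1": "POS", "P3": "POS", "P5": "POS", "P6": "POS",
    "G1": "POS", "G9": "POS", "G12": "POS", "G16": "POS",
    # Impaired cognition-control
    "P2": "COG", "P4": "COG", "G5": "COG", "G10": "COG", "G11": "COG",
    "G13": "COG", "G15": "COG", "N5": "COG", "N7": "COG",
    # Impulsive-hostile
    "P7": "HOS", "G8": "HOS", "G14": "HOS",
    # Distress: anxiety, guilt, tension, depression
    "G2": "DST", "G3": "DST", "G4": "DST", "G6": "DST",
    # Negative / withdrawn-disengaged
    "G7": "NEG", "N1": "NEG", "N2": "NEG", "N3": "NEG", "N4": "NEG",
    "N6": "NEG",
}


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered item codes plus the item -> domain assignment.

    Invariants (checked on construction): exactly 30 items, every item
    mapped to exactly one domain.
    """

    codes: tuple[str, ...] = PANSS_CODES
    domain_of: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_DOMAIN_OF)
    )

    def __post_init__(self) -> None:
        if len(self.codes) != 30 or len(set(self.codes)) != 30:
            raise ValueError("catalog must contain exactly 30 distinct items")
        missing = [c for c in self.codes if c not in self.domain_of]
        if missing:
            raise ValueError(f"items without a domain assignment: {missing}")
        extra = set(self.domain_of) - set(self.codes)
        if extra:
            raise ValueError(f"domain map covers unknown items: {sorted(extra)}")

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.domain_of.values())))

    def members(self, domain: str) -> list[str]:
        """Item codes belonging to ``domain``, in catalog order."""
        return [c for c in self.codes if self.domain_of[c] == domain]

    def index_of(self, code: str) -> int:
        return self.codes.index(code)


def default_catalog() -> ItemCatalog:
    """The five-domain catalog used throughout the package."""
    return ItemCatalog()
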