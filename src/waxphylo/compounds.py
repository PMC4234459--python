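"""Canonical leaf-wax compound definitions.

The analysis targets seven long-chain cuticular lipids: even-numbered
n-alkanoic acids (C24, C26, C28, C30) and odd-numbered n-alkanes
(C27, C29, C31).  Compound ids double as trait-table column suffixes
(``dD_C28_acid`` etc.).
"""

from __future__ import annotations

from dataclasses import dataclass

ACID = "acid"
ALKANE = "alkane"

_CANONICAL_CHAINS = {ACID: (24, 26, 28, 30), ALKANE: (27, 29, 31)}


@dataclass(frozen=True)
class CompoundSpec:
    """One leaf-wax homolog: compound class plus carbon chain length."""

    id: str
    compound_class: str
    chain_length: int

    def __post_init__(self) -> None:
        if self.compound_class not in (ACID, ALKANE):
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.chain_length <= 0:
            raise ValueError("chain_length must be positive")

    @property
    def column(self) -> str:
        """Trait-table column name holding this compound's dD value."""
        return f"dD_{self.id}"


def _make(cls: str, n: int) -> CompoundSpec:
    return CompoundSpec(id=f"C{n}_{cls}", compound_class=cls, chain_length=n)


#: The seven compounds measured per plant, acids first.
CANONICAL_COMPOUNDS: tuple[CompoundSpec, ...] = tuple(
    _make(cls, n) for cls in (ACID, ALKANE) for n in _CANONICAL_CHAINS[cls]
)

ACIDS: tuple[CompoundSpec, ...] = tuple(
    c for c in CANONICAL_COMPOUNDS if c.compound_class == ACID
)
ALKANES: tuple[CompoundSpec, ...] = tuple(
    c for c in CANONICAL_COMPOUNDS if c.compound_class == ALKANE
)

#: Major vascular-plant lineage classes, early-diverging first.
LINEAGES = (
    "Lycopod",
    "Fern",
    "Gymnosperm",
    "Magnoliid",
    "Eudicot",
    "MonocotMinus",
    "PoalesMinus",
    "BEP",
)

GROWTH_FORMS = ("tree", "shrub", "forb_herb", "graminoid", "climbing_vine")
PATHWAYS = ("C3", "C4", "CAM")


def by_id(compound_id: str) -> CompoundSpec:
    for c in CANONICAL_COMPOUNDS:
        if c.id == compound_id:
            return c
    raise KeyError(f"unknown compound id {compound_id!r}")
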