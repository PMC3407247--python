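"""Tier-3: directional intersection of the two screens' gene signatures.

The panel screen and the paired-lines screen each yield a sensitivity-
associated and a resistance-associated gene set.  The integrated signature
is the per-direction intersection — no re-weighting, no rank aggregation —
matched on gene symbol after case-normalisation, the only key the two array
platforms share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import ContractError

SCREEN_NAMES = ("primary_panel", "paired_lines")
DIRECTIONS = ("sensitivity_associated", "resistance_associated")


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSignature:
    """One screen's directional gene set."""

    screen_name: str
    direction: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.screen_name not in SCREEN_NAMES:
            raise ValueError(f"unknown screen {self.screen_name!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        canon = [_canon(g) for g in self.genes]
        if len(canon) != len(set(canon)):
            raise ValueError("duplicate gene symbols in signature")

    @classmethod
    def from_genes(
        cls, screen_name: str, direction: str, genes: Iterable[str]
    ) -> "GeneSignature":
        seen: dict[str, str] = {}
        for g in genes:
            seen.setdefault(_canon(g), g.strip())
        return cls(screen_name, direction, tuple(sorted(seen.values())))

    def canonical_genes(self) -> set[str]:
        return {_canon(g) for g in self.genes}


@dataclass(frozen=True)
class IntegratedSignature:
    """Per-direction overlap of the two screens, with full provenance."""

    sensitivity_overlap: frozenset[str]
    resistance_overlap: frozenset[str]
    provenance: tuple[GeneSignature, GeneSignature, GeneSignature, GeneSignature]

    def __post_init__(self) -> None:
        if self.sensitivity_overlap & self.resistance_overlap:
            raise ValueError("direction overlaps must be disjoint")


def intersect_signatures(
    panel_sens: GeneSignature,
    panel_res: GeneSignature,
    paired_sens: GeneSignature,
    paired_res: GeneSignature,
) -> IntegratedSignature:
    """Intersect the four directional signatures into the final product.

    Direction labels must match across screens (sensitivity with
    sensitivity, resistance with resistance); symbols are compared
    case-insensitively with surrounding whitespace stripped.
    """
    for sig, direction in (
        (panel_sens, "sensitivity_associated"),
        (panel_res, "resistance_associated"),
        (paired_sens, "sensitivity_associated"),
        (paired_res, "resistance_associated"),
    ):
        if sig.direction != direction:
            raise ContractError(
                f"signature {sig.screen_name}/{sig.direction} paired with "
                f"{direction} slot"
            )
    sens = frozenset(panel_sens.canonical_genes() & paired_sens.canonical_genes())
    res = frozenset(panel_res.canonical_genes() & paired_res.canonical_genes())
    sens -= res  # a symbol cannot sit in both directional overlaps
    return IntegratedSignature(
        sensitivity_overlap=sens,
        resistance_overlap=res,
        provenance=(panel_sens, panel_res, paired_sens, paired_res),
    )
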