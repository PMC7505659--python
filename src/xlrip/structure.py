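"""Mapping cross-links onto atomic structures and distance validation.

An amine-reactive cross-linker of the DSS/BS3 family bridges lysines whose
Cα atoms lie within roughly 30 Å, so a reported link whose minimum Cα–Cα
distance on a structure exceeds a cutoff (default 35 Å) counts as a
violation.  When a protein is present as several chain copies (paralogs,
duplicated chains), a link is satisfied if *any* copy pair satisfies it,
so the distance assigned to a link is the minimum over all copy pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, XlripError
from .fdr import CrossLink

logger = logging.getLogger("xlrip")


@dataclass(frozen=True)
class ChainMapEntry:
    """Maps one protein id onto one structure chain.

    ``residue_offset`` is added to a reported (endogenous-sequence) residue
    number to obtain the structure's residue numbering; it may be negative
    (e.g. when the construct carries an N-terminal tag absent from the
    deposited coordinates).
    """

    protein_id: str
    chain_id: str
    residue_offset: int = 0


class ChainMap:
    """Protein → chain assignments; a protein may map to several chains."""

    def __init__(self, entries: Iterable[ChainMapEntry]):
        self.entries = list(entries)
        if not self.entries:
            raise ConfigError("chain map is empty")
        seen = set()
        for e in self.entries:
            key = (e.protein_id, e.chain_id)
            if key in seen:
                raise ConfigError(f"duplicate chain-map entry {key}")
            seen.add(key)

    def chains_for(self, protein_id: str) -> list[ChainMapEntry]:
        return [e for e in self.entries if e.protein_id == protein_id]

    @property
    def chain_ids(self) -> set[str]:
        return {e.chain_id for e in self.entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StructureModel:
    """Cα coordinates per (chain, residue), in Å, 1-based residue numbers."""

    chains: dict[str, dict[int, np.ndarray]]
    source_id: str = ""

    def ca(self, chain_id: str, residue: int) -> np.ndarray | None:
        return self.chains.get(chain_id, {}).get(residue)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return StructureModel(
            chains={
                cid: {res: R @ xyz + t for res, xyz in residues.items()}
                for cid, residues in self.chains.items()
            },
            source_id=self.source_id,
        )


def map_link_distance(
    link: CrossLink, model: StructureModel, chain_map: ChainMap
) -> tuple[bool, float | None]:
    """Minimum Cα–Cα distance of a link over all chain-copy pairs.

    Returns ``(mappable, min_distance)``; a link is unmappable when no
    copy pair has both offset-corrected Cα atoms present in the structure.
    Unmappable is a value, not an error.
    """
    best: float | None = None
    for ea in chain_map.chains_for(link.protein_a):
        xa = model.ca(ea.chain_id, link.residue_a + ea.residue_offset)
        if xa is None:
            continue
        for eb in chain_map.chains_for(link.protein_b):
            xb = model.ca(eb.chain_id, link.residue_b + eb.residue_offset)
            if xb is None:
                continue
            d = float(np.linalg.norm(xa - xb))
            if best is None or d < best:
                best = d
    return (best is not None), best


@dataclass
class LinkDistance:
    """Per-link distance-mapping outcome."""

    link: CrossLink
    mappable: bool
    min_distance: float | None
    is_self: bool = False
    is_violation: bool | None = None


@dataclass
class DistanceSummary:
    """Violation-rate summary over structure-mappable links.

    ``violation_rate`` is n_violations / n_mappable; unmappable and
    self links are excluded from the denominator.  ``rate_defined`` is
    False when no link is mappable.
    """

    n_links: int
    n_mappable: int
    n_unmappable: int
    n_self_excluded: int
    n_violations: int
    cutoff: float
    violation_rate: float
    rate_defined: bool = True

    @property
    def violation_percent(self) -> float:
        """The rate as a percentage rounded to one decimal."""
        return round(100.0 * self.violation_rate, 1)


def violation_summary(
    reports: Sequence[LinkDistance], cutoff: float
) -> DistanceSummary:
    """Flag violations (min_distance strictly > cutoff) and summarize."""
    if cutoff <= 0:
        raise ConfigError("distance cutoff must be positive")
    considered = [r for r in reports if not r.is_self]
    n_self = len(reports) - len(considered)
    mappable = [r for r in considered if r.mappable]
    n_viol = 0
    for r in mappable:
        r.is_violation = r.min_distance > cutoff
        n_viol += int(r.is_violation)
    defined = len(mappable) > 0
    if not defined:
        logger.warning("violation_summary: zero mappable links, rate undefined")
    return DistanceSummary(
        n_links=len(considered),
        n_mappable=len(mappable),
        n_unmappable=len(considered) - len(mappable),
        n_self_excluded=n_self,
        n_violations=n_viol,
        cutoff=cutoff,
        violation_rate=(n_viol / len(mappable)) if defined else float("nan"),
        rate_defined=defined,
    )


def evaluate_links(
    links: Sequence[CrossLink],
    model: StructureModel,
    chain_map: ChainMap,
    cutoff: float,
) -> tuple[list[LinkDistance], DistanceSummary]:
    """Map every link, then summarize violations at ``cutoff``."""
    reports = []
    for link in links:
        mappable, dist = map_link_distance(link, model, chain_map)
        reports.append(
            LinkDistance(
                link=link, mappable=mappable, min_distance=dist, is_self=link.is_self
            )
        )
    summary = violation_summary(reports, cutoff)
    logger.info(
        "evaluate_links: %d links, %d mappable, %d violations (rate %.4f)",
        summary.n_links,
        summary.n_mappable,
        summary.n_violations,
        summary.violation_rate,
    )
    return reports, summary
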