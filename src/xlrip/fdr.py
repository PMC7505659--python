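"""k-fold-decoy error model, FDR curves, and cross-link aggregation.

With a decoy database k times the size of the target database, the
expected numbers of target-target (TT) hits containing wrongly identified
peptides follow from the observed decoy-class counts at a score
threshold::

    tf(TT) = TD / k - 2 DD / k**2     # exactly one wrong peptide
    ff(TT) = DD / k**2                # both peptides wrong

and the estimated FDR of the TT list is ``(tf + ff) / TT``.  ``tf`` is
clamped at zero: at small counts the subtraction can go negative while the
quantity it estimates is a nonnegative expected count.

CSMs are aggregated to unique residue-pair cross-links by keeping the best
scoring CSM per canonically ordered pair across both fragmentation
channels; the error model applies unchanged at the link level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .csm import CSMRecord
from .errors import ConfigError, RecordError, XlripError

logger = logging.getLogger("xlrip")

#: Deterministic channel preference when svm_scores tie during aggregation.
_CHANNEL_ORDER = {"HCD": 0, "ETD": 1}


@dataclass(frozen=True)
class DecoyCounts:
    """TT/TD/DD counts at (or above) one score threshold."""

    tt: int
    td: int
    dd: int
    k: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError(f"decoy ratio k must be positive, got {self.k}")
        if min(self.tt, self.td, self.dd) < 0:
            raise XlripError("decoy-class counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tt + self.td + self.dd


def expected_wrong_counts(c: DecoyCounts) -> tuple[float, float]:
    """Modeled counts of TT hits with one / both peptides wrong.

    Returns ``(tf, ff)`` un-rounded; ``tf`` clamped at 0.
    """
    tf = c.td / c.k - 2.0 * c.dd / c.k**2
    ff = c.dd / c.k**2
    return max(tf, 0.0), ff


def _score_of(item) -> float:
    s = getattr(item, "svm_score", None)
    if s is None:
        s = getattr(item, "best_svm_score", None)
    if s is None:
        raise XlripError("item has no svm_score; run scoring first")
    return s


def count_decoy_classes(items: Iterable, threshold: float, k: float) -> DecoyCounts:
    """TT/TD/DD counts over items with score >= threshold."""
    tt = td = dd = 0
    for item in items:
        if _score_of(item) >= threshold:
            cls = item.decoy_class
            if cls == "TT":
                tt += 1
            elif cls == "TD":
                td += 1
            else:
                dd += 1
    return DecoyCounts(tt, td, dd, k)


def fdr_at_threshold(
    items: Sequence, threshold: float, k: float
) -> tuple[DecoyCounts, float]:
    """Decoy counts and estimated FDR ``(tf + ff) / TT`` at one threshold.

    FDR is 0 (with a warning) when no TT item passes.
    """
    counts = count_decoy_classes(items, threshold, k)
    if counts.tt == 0:
        logger.warning("fdr_at_threshold: no TT items at threshold %g", threshold)
        return counts, 0.0
    tf, ff = expected_wrong_counts(counts)
    return counts, (tf + ff) / counts.tt


@dataclass
class FDRCurve:
    """Per-threshold decoy counts, modeled errors, and FDR.

    ``table`` rows are sorted by ascending threshold with columns
    threshold, tt, td, dd, tf, ff, fdr_raw, fdr_monotone.  ``fdr_monotone``
    is the running minimum of ``fdr_raw`` taken over all thresholds at or
    below each row's (the q-value convention), so it is nonincreasing as
    the threshold increases.
    """

    table: pd.DataFrame
    k: float

    def threshold_at_fdr(self, target_fdr: float) -> float:
        """Smallest threshold whose monotonized FDR is <= target."""
        ok = self.table[self.table["fdr_monotone"] <= target_fdr]
        if ok.empty:
            raise XlripError(f"no threshold reaches FDR <= {target_fdr}")
        return float(ok["threshold"].iloc[0])


def build_fdr_curve(
    items: Sequence, k: float, grid: Sequence[float] | None = None
) -> FDRCurve:
    """Tabulate decoy counts and estimated FDR over a threshold grid.

    The grid defaults to the sorted unique scores of ``items``.
    """
    items = list(items)
    if not items:
        raise XlripError("cannot build an FDR curve from zero records")
    scores = np.array([_score_of(it) for it in items])
    classes = np.array([it.decoy_class for it in items])
    if grid is None:
        thresholds = np.unique(scores)
    else:
        thresholds = np.unique(np.asarray(list(grid), dtype=float))

    # Count by suffix sums over score-sorted items: O(n log n) overall.
    order = np.argsort(scores)
    s_sorted = scores[order]
    rows = []
    for cls in ("TT", "TD", "DD"):
        flags = (classes[order] == cls).astype(int)
        suffix = np.concatenate([np.cumsum(flags[::-1])[::-1], [0]])
        idx = np.searchsorted(s_sorted, thresholds, side="left")
        rows.append(suffix[idx])
    tt_n, td_n, dd_n = rows

    tf = np.maximum(td_n / k - 2.0 * dd_n / k**2, 0.0)
    ff = dd_n / k**2
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = np.where(tt_n > 0, (tf + ff) / np.maximum(tt_n, 1), 0.0)
    fdr_monotone = np.minimum.accumulate(fdr_raw)

    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "tt": tt_n,
            "td": td_n,
            "dd": dd_n,
            "tf": tf,
            "ff": ff,
            "fdr_raw": fdr_raw,
            "fdr_monotone": fdr_monotone,
        }
    )
    return FDRCurve(table=table, k=k)


@dataclass
class CrossLink:
    """A unique residue-pair cross-link after CSM aggregation.

    The two sides are stored in canonical orientation (sorted by
    (protein_id, residue)), so the same physical link always produces the
    same record regardless of reporting order.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    best_svm_score: float
    channel_of_best: str
    n_csms: int
    decoy_class: str
    spectrum_id_of_best: str = ""

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.protein_a, self.residue_a), (self.protein_b, self.residue_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b and self.residue_a == self.residue_b


def canonical_pair(
    side1: tuple[str, int], side2: tuple[str, int]
) -> tuple[tuple[str, int], tuple[str, int]]:
    """Order two (protein, residue) sides deterministically."""
    return (side1, side2) if side1 <= side2 else (side2, side1)


def aggregate_links(
    records: Sequence[CSMRecord],
    ambiguity_groups: Mapping[str, str] | None = None,
) -> list[CrossLink]:
    """Collapse scored CSMs to one best CSM per unique residue pair.

    CSMs from both channels compete; ties on svm_score break by channel
    (HCD before ETD) then lexicographic spectrum id.  ``ambiguity_groups``
    maps protein ids to a shared group label (e.g. near-identical isoforms
    whose cross-links cannot be assigned to one member); links collapse
    within a group, which then appears as the link's protein id.
    """
    groups = ambiguity_groups or {}
    buckets: dict[tuple, list[CSMRecord]] = {}
    for i, rec in enumerate(records):
        if rec.svm_score is None:
            raise XlripError(f"record {rec.spectrum_id} has no svm_score")
        for pep in (rec.pep1, rec.pep2):
            if not pep.protein_id or pep.link_pos < 1:
                raise RecordError(
                    f"record {i} ({rec.spectrum_id}): missing residue assignment"
                )
        s1 = (groups.get(rec.pep1.protein_id, rec.pep1.protein_id), rec.pep1.link_pos)
        s2 = (groups.get(rec.pep2.protein_id, rec.pep2.protein_id), rec.pep2.link_pos)
        buckets.setdefault(canonical_pair(s1, s2), []).append(rec)

    links = []
    for (a, b), bucket in sorted(buckets.items()):
        best = min(
            bucket,
            key=lambda r: (-r.svm_score, _CHANNEL_ORDER[r.channel], r.spectrum_id),
        )
        links.append(
            CrossLink(
                protein_a=a[0],
                residue_a=a[1],
                protein_b=b[0],
                residue_b=b[1],
                best_svm_score=best.svm_score,
                channel_of_best=best.channel,
                n_csms=len(bucket),
                decoy_class=best.decoy_class,
                spectrum_id_of_best=best.spectrum_id,
            )
        )
    logger.info("aggregate_links: %d CSMs -> %d links", len(records), len(links))
    return links


def report_links(
    links: Sequence[CrossLink], threshold: float, k: float
) -> tuple[list[CrossLink], DecoyCounts, float]:
    """Final reported list: TT links at/above the reporting threshold.

    Decoy-containing links passing the threshold enter the decoy
    accounting (and hence the FDR estimate) but never the reported list.
    """
    counts, fdr = fdr_at_threshold(list(links), threshold, k)
    reported = [
        l for l in links if l.decoy_class == "TT" and l.best_svm_score >= threshold
    ]
    logger.info(
        "report_links: %d TT links at threshold %g (TT=%d TD=%d DD=%d, FDR=%.4f)",
        len(reported),
        threshold,
        counts.tt,
        counts.td,
        counts.dd,
        fdr,
    )
    return reported, counts, fdr
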