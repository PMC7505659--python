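"""Cross-link spectral match (CSM) records, prefiltering, and rescoring.

A CSM is one candidate assignment of a fragmentation spectrum to a pair of
cross-linked peptides.  Searches against a target database concatenated
with k randomized decoy sequences per target yield three decoy classes:
TT (both peptides target), TD (exactly one decoy), DD (both decoy).

Rescoring uses a linear SVM over seven per-CSM features — score
difference, percent of fragment ions matched, precursor charge state, and
the rank and length of each peptide — trained to separate TT from
decoy-containing (TD ∪ DD) matches.  The decision threshold is selected on
a held-out half of the data so that at most ``1 - specificity_target`` of
held-out decoy-containing CSMs score above it.  Separate classifiers are
fit per fragmentation channel (ETD, HCD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .config import RunConfig
from .errors import TrainingError, XlripError

logger = logging.getLogger("xlrip")

CHANNELS = ("ETD", "HCD")

#: Feature columns of the linear classifier, in matrix order.
FEATURE_NAMES = (
    "score_diff",
    "percent_ions_matched",
    "precursor_charge",
    "rank1",
    "rank2",
    "len1",
    "len2",
)


@dataclass(frozen=True)
class PeptideMatch:
    """One peptide of a cross-linked pair, as assigned by the search engine.

    ``link_pos`` is the 1-based residue number of the cross-linked residue
    in the protein's endogenous sequence.
    """

    sequence: str
    protein_id: str
    link_pos: int
    is_decoy: bool
    rank: int
    length: int
    score: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise XlripError(f"peptide rank must be >= 1, got {self.rank}")
        if self.length < 1:
            raise XlripError(f"peptide length must be >= 1, got {self.length}")


@dataclass
class CSMRecord:
    """One candidate cross-linked peptide-pair identification."""

    spectrum_id: str
    channel: str
    pep1: PeptideMatch
    pep2: PeptideMatch
    score_diff: float
    percent_ions_matched: float  # stored on the 0-1 scale
    precursor_charge: int
    svm_score: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise XlripError(f"unknown channel {self.channel!r}")
        # Accept percent-scale input (0-100) and normalize to 0-1 at ingest.
        if self.percent_ions_matched > 1.0:
            self.percent_ions_matched = self.percent_ions_matched / 100.0

    @property
    def decoy_class(self) -> str:
        """TT / TD / DD from the two per-peptide decoy flags."""
        n = int(self.pep1.is_decoy) + int(self.pep2.is_decoy)
        return ("TT", "TD", "DD")[n]

    @property
    def is_decoy_hit(self) -> bool:
        """True for decoy-containing matches (TD or DD)."""
        return self.pep1.is_decoy or self.pep2.is_decoy

    def features(self) -> np.ndarray:
        return np.array(
            [
                self.score_diff,
                self.percent_ions_matched,
                float(self.precursor_charge),
                float(self.pep1.rank),
                float(self.pep2.rank),
                float(self.pep1.length),
                float(self.pep2.length),
            ]
        )


def feature_matrix(records: Sequence[CSMRecord]) -> np.ndarray:
    """(n, 7) feature matrix in `FEATURE_NAMES` order."""
    if not records:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([r.features() for r in records])


def prefilter_csms(records: Iterable[CSMRecord], cfg: RunConfig) -> list[CSMRecord]:
    """Apply the initial CSM quality filter.

    Keeps records with both peptide scores strictly above
    ``cfg.min_peptide_score``, score difference strictly above
    ``cfg.min_score_diff``, and both peptide lengths inside the inclusive
    window ``[cfg.min_peptide_length, cfg.max_peptide_length]``.
    """
    records = list(records)
    lo, hi = cfg.min_peptide_length, cfg.max_peptide_length
    kept = [
        r
        for r in records
        if r.pep1.score > cfg.min_peptide_score
        and r.pep2.score > cfg.min_peptide_score
        and r.score_diff > cfg.min_score_diff
        and lo <= r.pep1.length <= hi
        and lo <= r.pep2.length <= hi
    ]
    logger.info("prefilter_csms: %d in, %d out", len(records), len(kept))
    if not kept and records:
        logger.warning("prefilter_csms removed every record")
    return kept


@dataclass
class ClassifierSpec:
    """A fitted linear decision function plus its operating point.

    ``weights``/``intercept`` act on z-standardized features
    (``(x - mean) / scale``), so the spec is self-contained: given raw
    features it reproduces the svm_score without the training data.
    ``channel`` is None for a pooled-channel model.
    """

    channel: str | None
    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    mean: np.ndarray
    scale: np.ndarray
    threshold: float
    achieved_specificity: float
    n_train: int = 0
    n_heldout_decoys: int = 0
    extras: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.scale
        return Z @ self.weights + self.intercept

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "feature_names": list(self.feature_names),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "mean": [float(m) for m in self.mean],
            "scale": [float(s) for s in self.scale],
            "threshold": float(self.threshold),
            "achieved_specificity": float(self.achieved_specificity),
            "n_train": int(self.n_train),
            "n_heldout_decoys": int(self.n_heldout_decoys),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        return cls(
            channel=d["channel"],
            feature_names=tuple(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            threshold=float(d["threshold"]),
            achieved_specificity=float(d["achieved_specificity"]),
            n_train=int(d.get("n_train", 0)),
            n_heldout_decoys=int(d.get("n_heldout_decoys", 0)),
        )


def _split_by_spectrum(
    records: Sequence[CSMRecord], seed: int
) -> tuple[list[int], list[int]]:
    """Random half split by spectrum id, so a spectrum never straddles halves."""
    spectra = sorted({r.spectrum_id for r in records})
    rng = np.random.default_rng(seed)
    rng.shuffle(spectra)
    train_ids = set(spectra[: len(spectra) // 2])
    train = [i for i, r in enumerate(records) if r.spectrum_id in train_ids]
    held = [i for i, r in enumerate(records) if r.spectrum_id not in train_ids]
    return train, held


def select_specificity_threshold(
    decoy_scores: np.ndarray, specificity_target: float
) -> float:
    """Smallest threshold t with frac(decoy_scores >= t) <= 1 - target.

    Candidates are the unique decoy scores themselves plus one value above
    the maximum, so the result is deterministic under ties.
    """
    scores = np.sort(np.asarray(decoy_scores, dtype=float))
    n = scores.size
    if n == 0:
        raise TrainingError("no decoy scores to set a specificity threshold")
    # integer comparison avoids float noise at exact fractions like 1/10
    max_above = int(np.floor((1.0 - specificity_target) * n + 1e-9))
    candidates = np.unique(scores)
    for t in candidates:
        if np.count_nonzero(scores >= t) <= max_above:
            return float(t)
    return float(np.nextafter(candidates[-1], np.inf))


def train_classifier(
    records: Sequence[CSMRecord],
    channel: str | None,
    cfg: RunConfig,
    min_class_records: int = 20,
    C: float = 1.0,
) -> ClassifierSpec:
    """Fit the linear SVM for one fragmentation channel.

    TT records are the positive class; decoy-containing (TD ∪ DD) records
    are the negative class.  The model is fit on a random half of the
    spectra (seeded from ``cfg.rng_seed``), features z-standardized on that
    half, and the decision threshold is the smallest value at which at most
    ``1 - cfg.specificity_target`` of held-out decoy-containing CSMs score
    above it.  All input records are annotated with their svm_score.

    Pass ``channel=None`` to pool both channels when one channel alone has
    too few records.
    """
    if channel is not None:
        subset = [r for r in records if r.channel == channel]
    else:
        subset = list(records)
    n_pos = sum(1 for r in subset if not r.is_decoy_hit)
    n_neg = len(subset) - n_pos
    if n_pos < min_class_records or n_neg < min_class_records:
        raise TrainingError(
            f"channel {channel}: {n_pos} TT and {n_neg} decoy-containing CSMs; "
            f"need >= {min_class_records} of each — consider pooling channels "
            "(channel=None)"
        )

    train_idx, held_idx = _split_by_spectrum(subset, cfg.rng_seed)
    X = feature_matrix(subset)
    y = np.array([0 if r.is_decoy_hit else 1 for r in subset])
    Xtr, ytr = X[train_idx], y[train_idx]
    if len(np.unique(ytr)) < 2:
        raise TrainingError(f"channel {channel}: training half has a single class")

    mean = Xtr.mean(axis=0)
    scale = Xtr.std(axis=0)
    scale[scale == 0] = 1.0

    svm = LinearSVC(C=C, dual=False, max_iter=10_000, tol=1e-6)
    svm.fit((Xtr - mean) / scale, ytr)
    spec = ClassifierSpec(
        channel=channel,
        feature_names=FEATURE_NAMES,
        weights=svm.coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        mean=mean,
        scale=scale,
        threshold=np.nan,
        achieved_specificity=np.nan,
        n_train=len(train_idx),
    )

    held_decoys = [i for i in held_idx if subset[i].is_decoy_hit]
    if not held_decoys:
        raise TrainingError(f"channel {channel}: no decoy-containing CSMs held out")
    d_scores = spec.decision_values(X[held_decoys])
    spec.threshold = select_specificity_threshold(d_scores, cfg.specificity_target)
    spec.n_heldout_decoys = len(held_decoys)
    spec.achieved_specificity = float(
        np.count_nonzero(d_scores < spec.threshold) / len(held_decoys)
    )

    score_csms(subset, spec)
    logger.info(
        "train_classifier[%s]: n=%d threshold=%.4f held-out specificity=%.4f",
        channel,
        len(subset),
        spec.threshold,
        spec.achieved_specificity,
    )
    return spec


def score_csms(
    records: Sequence[CSMRecord], model: ClassifierSpec
) -> list[CSMRecord]:
    """Annotate records with the model's decision value; order preserved."""
    records = list(records)
    if not records:
        return records
    if model.channel is not None:
        bad = {r.channel for r in records} - {model.channel}
        if bad:
            raise XlripError(
                f"model is for channel {model.channel}, records include {sorted(bad)}"
            )
    values = model.decision_values(feature_matrix(records))
    for r, v in zip(records, values):
        r.svm_score = float(v)
    return records
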