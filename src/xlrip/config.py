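"""Run-wide configuration.

All thresholds that control the analysis live in one flat record so that a
single file (plain ``key = value`` text) fully determines a run.  Defaults
are the published operating points of the protocol this package implements:
a 10:1 decoy:target database, a 90%-specificity classifier threshold, link
reporting at SVM score 1.5, a 35 Å Cα–Cα violation cutoff, and a 0.5-CPM
expression floor.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

logger = logging.getLogger("xlrip")


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with its default.

    Attributes
    ----------
    k_decoy_ratio:
        Ratio of decoy to target database size (k randomized sequences per
        target sequence).
    specificity_target:
        Held-out decoy specificity at which the CSM classifier threshold is
        selected.
    svm_report_threshold:
        SVM score above which aggregated cross-links are reported.
    distance_cutoff_angstrom:
        Cα–Cα distance above which a mapped cross-link counts as a
        violation (strict inequality).
    cpm_floor:
        Mean-CPM floor below which genes are dropped from the enrichment
        analysis (strict inequality).
    min_peptide_score / min_score_diff:
        CSM prefilter bounds; both strict ("above").
    min_peptide_length / max_peptide_length:
        Inclusive peptide-length window of the prefilter.
    rng_seed:
        Master seed; stages derive their own streams from it.
    """

    k_decoy_ratio: float = 10.0
    specificity_target: float = 0.90
    svm_report_threshold: float = 1.5
    distance_cutoff_angstrom: float = 35.0
    cpm_floor: float = 0.5
    min_peptide_score: float = 20.0
    min_score_diff: float = 0.0
    min_peptide_length: int = 4
    max_peptide_length: int = 25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_decoy_ratio <= 0:
            raise ConfigError("k_decoy_ratio must be positive")
        if not (0.0 < self.specificity_target <= 1.0):
            raise ConfigError("specificity_target must be in (0, 1]")
        if self.distance_cutoff_angstrom <= 0:
            raise ConfigError("distance_cutoff_angstrom must be positive")
        if self.cpm_floor < 0:
            raise ConfigError("cpm_floor must be nonnegative")
        if self.min_peptide_length < 1:
            raise ConfigError("min_peptide_length must be >= 1")
        if self.max_peptide_length < self.min_peptide_length:
            raise ConfigError("peptide length range is empty")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` config file; kwargs override the file."""
        values = dict(read_keyvalue_file(path))
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, raw in values.items():
            if key not in fields:
                raise ConfigError(f"unknown config key {key!r} in {path}")
            kwargs[key] = _coerce(raw, fields[key].type)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def log_effective(self) -> None:
        """One line per setting, so every run records its effective config."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %s", f.name, getattr(self, f.name))


def read_keyvalue_file(path: str | Path):
    """Parse a flat key-value text document (``key = value``, # comments)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        yield key.strip(), value.strip()


def _coerce(raw: str, typ) -> object:
    name = typ if isinstance(typ, str) else getattr(typ, "__name__", str(typ))
    try:
        if "int" in name:
            return int(raw)
        if "float" in name:
            return float(raw)
    except ValueError as exc:
        raise ConfigError(f"cannot parse {raw!r} as {name}") from exc
    return raw
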