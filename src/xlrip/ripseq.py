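"""Ribosome-IP sequencing (RIP-seq) enrichment analysis.

Transcripts co-purifying with an affinity-tagged ribosome-translocon
complex are compared against a mock purification and the total membrane
fraction.  Per gene, on the counts-per-million (CPM) scale::

    enrichment = (mean Flag-IP CPM - mean Ctrl-IP CPM) / mean input CPM

where "input" is the total membrane abundance.  Genes below a mean-CPM
floor (default 0.5, strict) are dropped before ranking.  Client sets are
then summarized by membrane-protein annotation: the number of predicted
transmembrane domains (TMDs) per protein and its functional category,
distinguishing multi-pass clients (>= 4 TMDs) from single-pass ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ConfigError, DataError, XlripError

logger = logging.getLogger("xlrip")

ROLES = ("flag_ip", "ctrl_ip", "input")

#: TMD count at or above which a membrane protein counts as multi-pass.
MULTIPASS_MIN_TMD = 4


@dataclass
class SampleSheet:
    """Sample roles and replicates; backed by a validated DataFrame."""

    frame: pd.DataFrame  # columns: sample_id, role, replicate, [batch]

    def __post_init__(self) -> None:
        required = {"sample_id", "role", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise DataError(f"duplicate sample ids: {sorted(set(dup))}")
        bad = set(self.frame["role"]) - set(ROLES)
        if bad:
            raise DataError(f"unknown roles {sorted(bad)}; expected {ROLES}")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise DataError("replicate numbers must be positive")

    def samples_for(self, role: str) -> list[str]:
        return list(self.frame.loc[self.frame["role"] == role, "sample_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def require_roles(self, roles: Sequence[str] = ROLES) -> None:
        for role in roles:
            if not self.samples_for(role):
                raise ConfigError(f"sample sheet has no sample with role {role!r}")


@dataclass
class CountMatrix:
    """Gene × sample counts (or CPM) with their sample sheet."""

    counts: pd.DataFrame  # index: gene ids; columns: sample ids
    sheet: SampleSheet
    unit: str = "counts"  # "counts" or "cpm"


def cpm(matrix: CountMatrix) -> CountMatrix:
    """Scale each column to sum to 1e6 (counts per million)."""
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"zero-sum count column(s): {list(zero.index)}")
    scaled = matrix.counts * (1e6 / totals)
    return CountMatrix(counts=scaled, sheet=matrix.sheet, unit="cpm")


@dataclass
class EnrichmentTable:
    """Per-gene role means, enrichment score, rank, and annotation join.

    ``frame`` columns: mean_flag_ip, mean_ctrl_ip, mean_input, mean_cpm,
    passes_floor, enrichment, rank (NaN where unranked), plus any joined
    annotation columns (is_secretory_membrane, n_tmd, category).
    """

    frame: pd.DataFrame
    floor: float
    floor_scope: str

    @property
    def ranked(self) -> pd.DataFrame:
        """Floor-passing, scored genes sorted by descending enrichment."""
        f = self.frame
        out = f[f["passes_floor"] & f["enrichment"].notna()]
        return out.sort_values(
            ["enrichment", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)


def enrichment_scores(
    matrix: CountMatrix,
    cfg: RunConfig,
    annotation: pd.DataFrame | None = None,
    floor_scope: str = "all",
) -> EnrichmentTable:
    """Score every gene: (mean Flag-IP − mean Ctrl-IP) / mean input, on CPM.

    Role means are taken across replicates on the CPM scale.  Genes whose
    mean input CPM is zero are left unscored rather than infinite.  The
    expression floor (strict ``> cfg.cpm_floor``) is evaluated on the mean
    CPM across all samples (``floor_scope="all"``) or input samples only
    (``"input"``).  ``annotation`` (gene_id, is_secretory_membrane, n_tmd,
    category) is joined when given; unannotated genes keep NaN.
    """
    if matrix.unit != "cpm":
        matrix = cpm(matrix)
    sheet = matrix.sheet
    sheet.require_roles()
    if floor_scope not in ("all", "input"):
        raise ConfigError(f"floor_scope must be 'all' or 'input', got {floor_scope!r}")

    c = matrix.counts
    means = {
        role: c[sheet.samples_for(role)].mean(axis=1) for role in ROLES
    }
    floor_cols = c.columns if floor_scope == "all" else sheet.samples_for("input")
    mean_cpm = c[list(floor_cols)].mean(axis=1)

    frame = pd.DataFrame(
        {
            "gene_id": c.index,
            "mean_flag_ip": means["flag_ip"].values,
            "mean_ctrl_ip": means["ctrl_ip"].values,
            "mean_input": means["input"].values,
            "mean_cpm": mean_cpm.values,
        }
    )
    frame["passes_floor"] = frame["mean_cpm"] > cfg.cpm_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (frame["mean_flag_ip"] - frame["mean_ctrl_ip"]) / frame["mean_input"]
    frame["enrichment"] = score.where(frame["mean_input"] > 0)
    n_unscored = int((frame["mean_input"] <= 0).sum())
    if n_unscored:
        logger.info("enrichment_scores: %d genes unscored (zero input CPM)", n_unscored)

    if annotation is not None:
        frame = frame.merge(annotation, on="gene_id", how="left")

    # Rank floor-passing scored genes by descending score, ties by gene id.
    eligible = frame["passes_floor"] & frame["enrichment"].notna()
    order = frame[eligible].sort_values(
        ["enrichment", "gene_id"], ascending=[False, True]
    )
    frame["rank"] = np.nan
    frame.loc[order.index, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    logger.info(
        "enrichment_scores: %d genes, %d pass floor, %d ranked",
        len(frame),
        int(frame["passes_floor"].sum()),
        len(order),
    )
    return EnrichmentTable(frame=frame, floor=cfg.cpm_floor, floor_scope=floor_scope)


def floor_filter(table: EnrichmentTable, cfg: RunConfig) -> EnrichmentTable:
    """Re-apply the expression floor (strict) and drop failing genes."""
    frame = table.frame[table.frame["mean_cpm"] > cfg.cpm_floor].reset_index(drop=True)
    if frame.empty:
        logger.warning("floor_filter: no gene passes the %g-CPM floor", cfg.cpm_floor)
    out = EnrichmentTable(
        frame=frame.assign(passes_floor=True), floor=cfg.cpm_floor,
        floor_scope=table.floor_scope,
    )
    return out


def client_set(
    table: EnrichmentTable,
    mode: str,
    value: float,
    membrane_only: bool = False,
) -> list[str]:
    """Select the most-enriched genes.

    ``mode="top_n"`` takes the ``value`` highest-ranked genes;
    ``mode="score_threshold"`` takes genes with enrichment strictly above
    ``value``.  ``membrane_only`` restricts the candidate pool to genes
    annotated as secretory-pathway membrane proteins.  Ties break by gene
    id via the ranking order.
    """
    ranked = table.ranked
    if membrane_only:
        if "is_secretory_membrane" not in ranked.columns:
            raise XlripError("membrane_only requires an annotation join")
        ranked = ranked[ranked["is_secretory_membrane"].fillna(False).astype(bool)]
    if mode == "top_n":
        n = int(value)
        if n < 0:
            raise ConfigError("top_n value must be nonnegative")
        if n > len(ranked):
            logger.warning(
                "client_set: requested top %d of %d genes; returning all", n, len(ranked)
            )
        return list(ranked["gene_id"].iloc[:n])
    if mode == "score_threshold":
        return list(ranked.loc[ranked["enrichment"] > value, "gene_id"])
    raise ConfigError(f"unknown client_set mode {mode!r}")


#: Default TMD histogram bins: integer counts 1..13 and a pooled "14+" bin.
DEFAULT_TMD_BINS = tuple(range(1, 14)) + ("14+",)


def _tmd_bin(n_tmd: float, bins: tuple) -> object | None:
    if pd.isna(n_tmd):
        return None
    n = int(n_tmd)
    numeric = [b for b in bins if isinstance(b, int)]
    if n in numeric:
        return n
    top = max(numeric) if numeric else 0
    if n > top and any(isinstance(b, str) for b in bins):
        return f"{top + 1}+"
    return None


@dataclass
class TMDSummary:
    """Client vs background TMD histograms and category tabulation."""

    proportions: pd.DataFrame  # index: bin; columns: client, background
    multipass_fraction_client: float
    multipass_fraction_background: float
    category_counts: pd.Series
    n_client: int
    n_client_unannotated: int


def tmd_summary(
    clients: Sequence[str],
    table: EnrichmentTable,
    bins: tuple = DEFAULT_TMD_BINS,
) -> TMDSummary:
    """TMD-count distribution of a client set vs the floor-passing background.

    Proportions are computed over annotated membrane proteins (n_tmd >= 1)
    in each set; unannotated client genes are counted separately.  Also
    reports the multi-pass (>= 4 TMD) fraction of each set and the
    functional-category tabulation of the clients.
    """
    frame = table.frame
    if "n_tmd" not in frame.columns:
        raise XlripError("tmd_summary requires an annotation join (n_tmd column)")
    background = frame[frame["passes_floor"]]
    client_rows = frame[frame["gene_id"].isin(set(clients))]
    n_unannot = int(client_rows["n_tmd"].isna().sum())

    def histogram(rows: pd.DataFrame) -> tuple[pd.Series, float]:
        tm = rows.loc[rows["n_tmd"].fillna(0) >= 1]
        assigned = tm["n_tmd"].map(lambda v: _tmd_bin(v, bins)).dropna()
        counts = assigned.value_counts()
        counts = counts.reindex(list(bins), fill_value=0)
        total = counts.sum()
        props = counts / total if total else counts.astype(float)
        multipass = (
            float((tm["n_tmd"] >= MULTIPASS_MIN_TMD).mean()) if len(tm) else float("nan")
        )
        return props, multipass

    client_props, client_multi = histogram(client_rows)
    bg_props, bg_multi = histogram(background)
    categories = (
        client_rows["category"].dropna().value_counts()
        if "category" in client_rows.columns
        else pd.Series(dtype=int)
    )
    return TMDSummary(
        proportions=pd.DataFrame(
            {"client": client_props, "background": bg_props}
        ),
        multipass_fraction_client=client_multi,
        multipass_fraction_background=bg_multi,
        category_counts=categories,
        n_client=len(client_rows),
        n_client_unannotated=n_unannot,
    )


def batch_center(matrix: CountMatrix) -> CountMatrix:
    """Remove additive per-batch offsets in log1p-CPM space.

    For each gene, every batch's samples are shifted so the batch mean
    equals the across-batch mean, then the values are mapped back to the
    CPM scale (clipped at 0).  A light-weight stand-in for model-based
    batch correction: it assumes batches differ by gene-wise offsets and
    that batch labels are not confounded with sample roles.  A sheet
    without a ``batch`` column (or with a single batch) passes through
    unchanged.
    """
    sheet = matrix.sheet
    if "batch" not in sheet.frame.columns:
        return matrix
    batches = sheet.frame.set_index("sample_id")["batch"]
    labels = [b for b in batches.unique() if str(b).strip() != ""]
    if len(labels) < 2:
        return matrix
    if matrix.unit != "cpm":
        matrix = cpm(matrix)
    log_cpm = np.log1p(matrix.counts)
    overall = log_cpm.mean(axis=1)
    adjusted = log_cpm.copy()
    for label in labels:
        cols = [s for s in matrix.counts.columns if batches.get(s) == label]
        offset = log_cpm[cols].mean(axis=1) - overall
        adjusted[cols] = log_cpm[cols].sub(offset, axis=0)
    centered = np.expm1(adjusted).clip(lower=0.0)
    logger.info("batch_center: centered %d batches", len(labels))
    return CountMatrix(counts=centered, sheet=sheet, unit="cpm")


def log2_display(score: np.ndarray | pd.Series) -> np.ndarray:
    """Signed log2 display transform, sign(x)·log2(1+|x|).

    Purely for plotting: the enrichment score itself can be negative, so a
    plain log2 is undefined; every analysis quantity uses the raw score.
    """
    x = np.asarray(score, dtype=float)
    return np.sign(x) * np.log2(1.0 + np.abs(x))
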