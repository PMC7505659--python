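"""Readers and writers for every tabular and structural format.

Tables are tab-delimited UTF-8 text with a header row; fields containing
tabs are rejected rather than quoted, so a written file is always readable
by a plain split on tabs.  Structures are PDB or mmCIF, parsed with gemmi.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .csm import CSMRecord, PeptideMatch
from .errors import DataError, FormatError, RecordError, SchemaError
from .fdr import CrossLink
from .ripseq import CountMatrix, SampleSheet
from .structure import ChainMap, ChainMapEntry, LinkDistance, StructureModel

logger = logging.getLogger("xlrip")

_CSM_COLUMNS = [
    "spectrum_id",
    "channel",
    "pep1_sequence",
    "pep1_protein",
    "pep1_link_pos",
    "pep1_is_decoy",
    "pep1_rank",
    "pep1_length",
    "pep1_score",
    "pep2_sequence",
    "pep2_protein",
    "pep2_link_pos",
    "pep2_is_decoy",
    "pep2_rank",
    "pep2_length",
    "pep2_score",
    "score_diff",
    "percent_ions_matched",
    "precursor_charge",
]

_TRUE_FLAGS = {"1", "true", "t", "yes", "decoy"}
_FALSE_FLAGS = {"0", "false", "f", "no", "target"}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc


def _write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    for col in frame.columns:
        if frame[col].dtype == object and frame[col].astype(str).str.contains("\t").any():
            raise DataError(f"column {col!r} contains a tab character; refusing to write")
    frame.to_csv(path, sep="\t", index=False)


def _parse_decoy_flag(raw: str, row: int, column: str) -> bool:
    v = raw.strip().lower()
    if v in _TRUE_FLAGS:
        return True
    if v in _FALSE_FLAGS:
        return False
    raise RecordError(f"row {row}: unknown decoy flag {raw!r} in column {column}")


def read_csm_table(path: str | Path, channel: str | None = None) -> list[CSMRecord]:
    """Read a CSM TSV; ``channel`` overrides/supplies the channel column.

    The decoy class of each record is derived from the two per-peptide
    decoy flags.  Rows with missing required fields raise a RecordError
    naming the row; a missing column raises a SchemaError naming it.
    """
    frame = _read_tsv(path)
    required = [c for c in _CSM_COLUMNS if c != "channel" or channel is None]
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"CSM table {path} lacks required column {col!r}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = row._asdict()
        for col in required:
            if str(row[col]).strip() == "":
                raise RecordError(f"row {i}: missing value in column {col!r}")
        try:
            peps = [
                PeptideMatch(
                    sequence=row[f"pep{j}_sequence"],
                    protein_id=row[f"pep{j}_protein"],
                    link_pos=int(row[f"pep{j}_link_pos"]),
                    is_decoy=_parse_decoy_flag(row[f"pep{j}_is_decoy"], i, f"pep{j}_is_decoy"),
                    rank=int(row[f"pep{j}_rank"]),
                    length=int(row[f"pep{j}_length"]),
                    score=float(row[f"pep{j}_score"]),
                )
                for j in (1, 2)
            ]
            rec = CSMRecord(
                spectrum_id=row["spectrum_id"],
                channel=channel if channel is not None else row["channel"],
                pep1=peps[0],
                pep2=peps[1],
                score_diff=float(row["score_diff"]),
                percent_ions_matched=float(row["percent_ions_matched"]),
                precursor_charge=int(row["precursor_charge"]),
            )
            if "svm_score" in frame.columns and str(row.get("svm_score", "")).strip():
                rec.svm_score = float(row["svm_score"])
        except RecordError:
            raise
        except (ValueError, KeyError) as exc:
            raise RecordError(f"row {i}: {exc}") from exc
        records.append(rec)
    logger.info("read_csm_table: %d records from %s", len(records), path)
    return records


def write_csm_table(records: Sequence[CSMRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "spectrum_id": r.spectrum_id,
            "channel": r.channel,
            "score_diff": repr(r.score_diff),
            "percent_ions_matched": repr(r.percent_ions_matched),
            "precursor_charge": r.precursor_charge,
        }
        for j, pep in ((1, r.pep1), (2, r.pep2)):
            row.update(
                {
                    f"pep{j}_sequence": pep.sequence,
                    f"pep{j}_protein": pep.protein_id,
                    f"pep{j}_link_pos": pep.link_pos,
                    f"pep{j}_is_decoy": int(pep.is_decoy),
                    f"pep{j}_rank": pep.rank,
                    f"pep{j}_length": pep.length,
                    f"pep{j}_score": repr(pep.score),
                }
            )
        if r.svm_score is not None:
            row["svm_score"] = repr(r.svm_score)
        rows.append(row)
    cols = _CSM_COLUMNS + (["svm_score"] if rows and "svm_score" in rows[0] else [])
    _write_tsv(pd.DataFrame(rows, columns=cols), path)
    logger.info("write_csm_table: %d records to %s", len(records), path)


def read_chain_map(path: str | Path) -> ChainMap:
    frame = _read_tsv(path)
    for col in ("protein_id", "chain_id"):
        if col not in frame.columns:
            raise SchemaError(f"chain map {path} lacks column {col!r}")
    entries = [
        ChainMapEntry(
            protein_id=row["protein_id"],
            chain_id=row["chain_id"],
            residue_offset=int(row.get("residue_offset", "0") or 0),
        )
        for _, row in frame.iterrows()
    ]
    return ChainMap(entries)


def write_chain_map(chain_map: ChainMap, path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id,
                    "chain_id": e.chain_id,
                    "residue_offset": e.residue_offset,
                }
                for e in chain_map
            ]
        ),
        path,
    )


def read_structure(path: str | Path, chain_map: ChainMap) -> StructureModel:
    """Parse Cα coordinates from a PDB/mmCIF file (first model only).

    Residues lacking a Cα atom are omitted.  Chain-map chains absent from
    the file are warned about and skipped, never fatal.
    """
    if chain_map is None or len(chain_map) == 0:
        raise DataError("chain map is empty")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"structure {path} contains no models")
    chains: dict[str, dict[int, np.ndarray]] = {}
    for chain in st[0]:
        residues: dict[int, np.ndarray] = {}
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is not None:
                residues[res.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
        if residues:
            chains[chain.name] = residues
    missing = chain_map.chain_ids - set(chains)
    for cid in sorted(missing):
        logger.warning("read_structure: chain %r in chain map absent from %s", cid, path)
    logger.info(
        "read_structure: %d chains, %d Cα atoms from %s",
        len(chains),
        sum(len(c) for c in chains.values()),
        path,
    )
    return StructureModel(chains=chains, source_id=st.name or Path(path).stem)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = _read_tsv(path)
    if "replicate" in frame.columns:
        frame["replicate"] = frame["replicate"].astype(int)
    return SampleSheet(frame=frame)


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a genes × samples TSV of nonnegative integer counts.

    Columns are matched to the sheet by sample id; a column the sheet does
    not know is an error, as are duplicate gene ids and negative counts.
    """
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise SchemaError(f"count table {path} needs a gene id column plus samples")
    gene_col = frame.columns[0]
    genes = frame[gene_col]
    if genes.duplicated().any():
        dup = sorted(set(genes[genes.duplicated()]))
        raise DataError(f"duplicate gene id(s) in {path}: {dup}")
    sample_cols = [c for c in frame.columns[1:]]
    unknown = [c for c in sample_cols if c not in set(sheet.sample_ids)]
    if unknown:
        raise DataError(f"count column(s) not in sample sheet: {unknown}")
    counts = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for col in sample_cols:
        try:
            values = pd.to_numeric(frame[col].values)
        except (ValueError, TypeError) as exc:
            raise DataError(f"non-numeric count in sample {col!r}") from exc
        neg = np.asarray(values) < 0
        if neg.any():
            gene = genes.iloc[int(np.argmax(neg))]
            raise DataError(f"negative count for gene {gene!r} in sample {col!r}")
        counts[col] = values
    logger.info("read_counts: %d genes × %d samples from %s", *counts.shape, path)
    return CountMatrix(counts=counts, sheet=sheet)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    _write_tsv(matrix.counts.reset_index(), path)


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path)
    for col in ("gene_id", "is_secretory_membrane", "n_tmd"):
        if col not in frame.columns:
            raise SchemaError(f"annotation {path} lacks column {col!r}")
    frame["n_tmd"] = frame["n_tmd"].astype(int)
    frame["is_secretory_membrane"] = frame["is_secretory_membrane"].map(
        lambda v: _parse_decoy_flag(str(v), -1, "is_secretory_membrane")
    )
    bad = frame[(frame["n_tmd"] > 0) & ~frame["is_secretory_membrane"]]
    if len(bad):
        raise DataError(
            f"{len(bad)} gene(s) carry TMDs but are not flagged as membrane proteins"
        )
    return frame


def write_links(links: Sequence[CrossLink], path: str | Path) -> None:
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_a": l.protein_a,
                    "residue_a": l.residue_a,
                    "protein_b": l.protein_b,
                    "residue_b": l.residue_b,
                    "best_svm_score": repr(l.best_svm_score),
                    "channel_of_best": l.channel_of_best,
                    "n_csms": l.n_csms,
                    "decoy_class": l.decoy_class,
                    "spectrum_id_of_best": l.spectrum_id_of_best,
                }
                for l in links
            ],
            columns=[
                "protein_a",
                "residue_a",
                "protein_b",
                "residue_b",
                "best_svm_score",
                "channel_of_best",
                "n_csms",
                "decoy_class",
                "spectrum_id_of_best",
            ],
        ),
        path,
    )


def read_links(path: str | Path) -> list[CrossLink]:
    frame = _read_tsv(path)
    required = {"protein_a", "residue_a", "protein_b", "residue_b", "best_svm_score"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"link table {path} lacks column(s) {sorted(missing)}")
    return [
        CrossLink(
            protein_a=row["protein_a"],
            residue_a=int(row["residue_a"]),
            protein_b=row["protein_b"],
            residue_b=int(row["residue_b"]),
            best_svm_score=float(row["best_svm_score"]),
            channel_of_best=row.get("channel_of_best", "HCD"),
            n_csms=int(row.get("n_csms", 1) or 1),
            decoy_class=row.get("decoy_class", "TT"),
            spectrum_id_of_best=row.get("spectrum_id_of_best", ""),
        )
        for _, row in frame.iterrows()
    ]


def write_distance_report(
    reports: Iterable[LinkDistance], path: str | Path
) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "protein_a": r.link.protein_a,
                "residue_a": r.link.residue_a,
                "protein_b": r.link.protein_b,
                "residue_b": r.link.residue_b,
                "mappable": int(r.mappable),
                "min_distance": "" if r.min_distance is None else repr(r.min_distance),
                "is_self": int(r.is_self),
                "is_violation": "" if r.is_violation is None else int(r.is_violation),
            }
        )
    _write_tsv(pd.DataFrame(rows), path)
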