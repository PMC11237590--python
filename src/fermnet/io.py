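"""Tabular and graph I/O for the pipeline.

Three tables drive everything: an ASV count table (samples x ASVs, integer
reads), a taxonomy table (kingdom..genus per ASV) and per-sample metadata
(study id, sampling time in days, control flags).  ASV identity across
studies is exact sequence-string equality, so the ASV id column is expected
to hold either the amplicon sequence itself or a stable alias that is
consistent across studies.

Dialect: TSV, UTF-8, mandatory header row, '.' decimal separator.  Count
tables are stored samples-as-rows; BIOM v1 (JSON) stores observations as
rows and is transposed on read.  Networks go to GraphML (via networkx) or
to node/edge TSVs with lexicographically ordered endpoints so output is
byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

METADATA_COLUMNS = ("sample_id", "study_id", "time_days", "is_control", "is_inoculated")


class ParseError(ValueError):
    """A file could not be parsed in its declared format."""


class ValidationError(ValueError):
    """A parsed table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class CountTable:
    """Integer read counts, samples x ASVs.

    ``data`` is a pandas DataFrame with sample ids as the index and ASV ids
    as columns.  Counts must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "ASV")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.any(values < 0):
                raise ValidationError("counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
        self.data = self.data.astype(np.int64, copy=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_depths(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class TaxonomyTable:
    """ASV id -> six-rank lineage; missing ranks are explicit ``None``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ASV")
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy table lacks rank columns: {missing}")
        self.data = self.data.loc[:, list(RANKS)].astype(object)
        # normalize empty strings / NaN to None so "missing" is unambiguous
        self.data = self.data.where(
            self.data.notna() & (self.data != ""), other=None
        )

    def rank_of(self, asv_id: str, rank: str) -> str | None:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        if asv_id not in self.data.index:
            return None
        return self.data.at[asv_id, rank]


@dataclass
class SampleMetadata:
    """Per-sample study id, sampling time (days) and control flags."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("study_id", "time_days", "is_control"):
            if col not in self.data.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        if "is_inoculated" not in self.data.columns:
            self.data = self.data.assign(is_inoculated=False)
        self.data["time_days"] = pd.to_numeric(self.data["time_days"])
        if (self.data["time_days"] < 0).any():
            raise ValidationError("time_days must be non-negative")
        for flag in ("is_control", "is_inoculated"):
            self.data[flag] = self.data[flag].astype(bool)
        self.data.index.name = "sample_id"

    def require_samples(self, sample_ids) -> None:
        """Every sample of a CountTable must have a metadata row."""
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {sorted(missing)[:5]}"
            )

    def time_of(self, sample_ids) -> np.ndarray:
        self.require_samples(sample_ids)
        return self.data.loc[list(sample_ids), "time_days"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty file: {path}")
    try:
        return pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a count table from TSV (samples as rows) or BIOM v1 JSON.

    BIOM stores observations (ASVs) as rows; the result is transposed to the
    package-wide samples x ASVs orientation.
    """
    if format == "tsv":
        raw = _read_tsv(path)
        try:
            numeric = raw.astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric count in {path}: {exc}") from exc
        numeric.index.name = "sample_id"
        return CountTable(numeric)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_biom(path) -> CountTable:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse BIOM JSON {path}: line {exc.lineno}") from exc
    try:
        obs_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        matrix = np.zeros(shape, dtype=float)
        if doc.get("matrix_type", "sparse") == "dense":
            matrix[:] = np.asarray(doc["data"], dtype=float)
        else:
            for r, c, v in doc["data"]:
                matrix[r, c] = v
    except (KeyError, TypeError, IndexError) as exc:
        raise ParseError(f"malformed BIOM document {path}: {exc}") from exc
    frame = pd.DataFrame(matrix.T, index=sample_ids, columns=obs_ids)
    frame.index.name = "sample_id"
    return CountTable(frame)


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        table.data.to_csv(path, sep="\t", index_label="sample_id")
        return
    if format == "biom":
        counts = table.counts.T  # observations x samples
        rows, cols = np.nonzero(counts)
        doc = {
            "id": "fermnet count table",
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "fermnet",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(counts.shape),
            "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [[int(r), int(c), int(counts[r, c])] for r, c in zip(rows, cols)],
        }
        path.write_text(json.dumps(doc))
        return
    raise ValueError(f"unknown count-table format {format!r}")


def read_taxonomy(path) -> TaxonomyTable:
    raw = _read_tsv(path)
    unknown = set(raw.columns) - set(RANKS)
    if unknown:
        raise ValidationError(f"unknown taxonomy columns: {sorted(unknown)}")
    raw.index.name = "asv_id"
    return TaxonomyTable(raw)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.data.to_csv(path, sep="\t", index_label="asv_id", na_rep="")


def read_metadata(path) -> SampleMetadata:
    raw = _read_tsv(path)
    known = set(METADATA_COLUMNS) - {"sample_id"}
    unknown = set(raw.columns) - known
    if unknown:
        raise ValidationError(f"unknown metadata columns: {sorted(unknown)}")
    raw.index.name = "sample_id"
    frame = raw.copy()
    for flag in ("is_control", "is_inoculated"):
        if flag in frame.columns:
            frame[flag] = frame[flag].map(
                {"True": True, "False": False, "1": True, "0": False,
                 "true": True, "false": False}
            )
            if frame[flag].isna().any():
                raise ValidationError(f"non-boolean value in column {flag!r}")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Undirected edges are stored with lexicographically ordered endpoints."""
    return (u, v) if u <= v else (v, u)


def write_network(net, path, format: str = "graphml") -> None:
    """Write an association or core network.

    ``net`` may be an AssociationNetwork/CoreNetwork (anything exposing a
    ``graph`` attribute) or a bare networkx Graph.  ``edge_tsv`` emits one
    row per undirected edge with canonically ordered ids; ``node_tsv`` one
    row per node with its attributes.
    """
    graph = net if isinstance(net, nx.Graph) else net.graph
    path = Path(path)
    if format == "graphml":
        out = nx.Graph(**graph.graph)
        for node, attrs in graph.nodes(data=True):
            out.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in graph.edges(data=True):
            a, b = canonical_edge(u, v)
            out.add_edge(a, b, **{k: _graphml_scalar(v2) for k, v2 in attrs.items()})
        nx.write_graphml(out, path)
        return
    if format == "edge_tsv":
        records = []
        for u, v, attrs in graph.edges(data=True):
            a, b = canonical_edge(u, v)
            records.append({"source": a, "target": b, **attrs})
        frame = pd.DataFrame(records, columns=_edge_columns(graph))
        frame = frame.sort_values(["source", "target"]) if len(frame) else frame
        frame.to_csv(path, sep="\t", index=False)
        return
    if format == "node_tsv":
        records = [{"asv_id": n, **attrs} for n, attrs in graph.nodes(data=True)]
        frame = pd.DataFrame(records)
        if len(frame):
            frame = frame.sort_values("asv_id")
        frame.to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown network format {format!r}")


def _graphml_scalar(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def _edge_columns(graph) -> list[str]:
    cols = ["source", "target"]
    seen: set[str] = set()
    for _, _, attrs in graph.edges(data=True):
        for key in attrs:
            if key not in seen:
                seen.add(key)
                cols.append(key)
    return cols


def read_network(path) -> nx.Graph:
    """Read back a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(Path(path))
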