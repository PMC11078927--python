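"""Readers and writers for every external representation the pipeline touches.

Tabular formats are TSV with a mandatory header row; gene identifiers are
treated as opaque, case-sensitive symbols (leading/trailing whitespace is
stripped, nothing else is ever rewritten). Networks travel as GraphML,
gene sets as GMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CountMatrix",
    "EdgeRecord",
    "GeneSet",
    "GeneSetCollection",
    "read_count_matrix",
    "write_count_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gene_sets",
    "read_physical_pairs",
    "read_qpcr_table",
    "write_network_graphml",
    "EDGE_DIALECTS",
]

META_COLUMNS = ("sample_id", "tissue", "condition", "batch")
CONDITIONS = ("control", "case")


class FormatError(ValueError):
    """Raised when an input file violates its documented layout."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x samples integer read counts plus per-sample metadata.

    ``counts`` is indexed by gene symbol with one column per sample;
    ``sample_meta`` is indexed by sample id with columns tissue,
    condition (``control``/``case``) and batch.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        cols = self.counts.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                flat = np.asarray(arr, dtype=float)
                if np.any(flat != np.floor(flat)) or np.any(~np.isfinite(flat)):
                    g, s = np.argwhere(flat != np.floor(flat))[0]
                    raise FormatError(
                        f"non-integer count at gene {idx[g]!r}, sample {cols[s]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
                )
        missing = [c for c in ("tissue", "condition", "batch") if c not in self.sample_meta.columns]
        if missing:
            raise FormatError(f"sample metadata lacks column(s): {missing}")
        absent = [s for s in cols if s not in self.sample_meta.index]
        if absent:
            raise FormatError(f"samples without metadata record: {absent}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(
                f"condition must be one of {CONDITIONS}, got {sorted(bad)}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return CountMatrix(self.counts[keep].copy(), self.sample_meta.loc[keep].copy())

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["tissue"] == tissue]
        if len(keep) == 0:
            raise ValueError(f"no samples with tissue {tissue!r}")
        return self.subset_samples(keep)

    def samples_of(self, condition: str) -> list[str]:
        mask = self.sample_meta.loc[self.sample_ids, "condition"] == condition
        return [s for s, m in zip(self.sample_ids, mask) if m]

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts) and self.sample_meta.loc[
            self.sample_ids, list(self.sample_meta.columns)
        ].equals(other.sample_meta.loc[other.sample_ids, list(self.sample_meta.columns)])


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample-metadata TSV."""
    path, meta_path = Path(path), Path(meta_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = header[1:]
    seen: set[str] = set()
    for s in sample_cols:
        if s in seen:
            raise FormatError(f"duplicate sample identifier in header: {s!r}")
        seen.add(s)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicate gene identifier: {dup!r}")
    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            gene = raw.index[vals.isna()][0]
            raise FormatError(
                f"non-numeric count at gene {gene!r}, sample {col!r}"
            )
        frac = vals != np.floor(vals)
        if frac.any():
            gene = raw.index[frac][0]
            raise FormatError(
                f"non-integer count at gene {gene!r}, sample {col!r}: {raw.loc[gene, col]}"
            )
        if (vals < 0).any():
            gene = raw.index[vals < 0][0]
            raise FormatError(f"negative count at gene {gene!r}, sample {col!r}")
        counts[col] = vals.astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata file lacks column(s): {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id in metadata: {dup!r}")
    meta = meta.set_index("sample_id")
    return CountMatrix(counts, meta)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        meta = cm.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# TF -> target edge lists
# ---------------------------------------------------------------------------

MODES = ("activation", "repression", "unknown", "ambiguous")


@dataclass(frozen=True)
class EdgeRecord:
    """One TF -> target regulation with provenance.

    mode is one of activation / repression / unknown / ambiguous;
    sources records which database(s) reported the edge; confidence
    carries a database-specific grade (e.g. a DoRothEA letter) when present.
    """

    regulator: str
    target: str
    mode: str = "unknown"
    sources: frozenset = field(default_factory=frozenset)
    confidence: str | None = None

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise FormatError("edge with empty regulator or target symbol")
        if self.mode not in MODES:
            raise FormatError(f"unknown edge mode {self.mode!r}")
        if not self.sources:
            raise FormatError("edge with empty source set")


def _normalize_mode(raw: str | None) -> str:
    if raw is None:
        return "unknown"
    token = str(raw).strip().lower()
    if token in ("", "nan", "none"):
        return "unknown"
    if token in MODES:
        return token
    return "unknown"


# dialect -> (required columns, row -> (regulator, target, mode, confidence))
EDGE_DIALECTS = {
    "trrust": ("TF", "target", "mode", "PMIDs"),
    "regnetwork": ("regulator", "regulator_id", "target", "target_id"),
    "dorothea": ("TF", "confidence", "target", "mor"),
    "generic3col": ("regulator", "target", "mode"),
}


def read_edge_list(
    path: str | Path,
    dialect: str,
    source: str | None = None,
) -> list[EdgeRecord]:
    """Parse a TF->target TSV in one of the documented dialects.

    ``source`` overrides the provenance label (defaults to the dialect name).
    An empty file (header only, or zero bytes) yields an empty list.
    """
    if dialect not in EDGE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(EDGE_DIALECTS)}")
    label = source or dialect
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    required = EDGE_DIALECTS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{dialect} edge list {path} lacks mandatory column(s): {missing}"
        )
    records: list[EdgeRecord] = []
    for _, row in df.iterrows():
        if dialect == "trrust":
            reg, tgt = row["TF"], row["target"]
            mode, conf = _normalize_mode(row["mode"]), None
        elif dialect == "regnetwork":
            reg, tgt = row["regulator"], row["target"]
            mode, conf = "unknown", None
        elif dialect == "dorothea":
            reg, tgt = row["TF"], row["target"]
            mor = row["mor"]
            try:
                mor_val = float(mor)
            except (TypeError, ValueError):
                mor_val = np.nan
            if np.isnan(mor_val) or mor_val == 0:
                mode = "unknown"
            else:
                mode = "activation" if mor_val > 0 else "repression"
            conf = None if pd.isna(row["confidence"]) else str(row["confidence"]).strip()
        else:  # generic3col
            reg, tgt = row["regulator"], row["target"]
            mode, conf = _normalize_mode(row["mode"]), None
        records.append(
            EdgeRecord(
                regulator=str(reg).strip(),
                target=str(tgt).strip(),
                mode=mode,
                sources=frozenset({label}),
                confidence=conf,
            )
        )
    return records


def write_edge_list(records: Iterable[EdgeRecord], path: str | Path) -> None:
    """Write edges in the generic3col dialect (regulator, target, mode)."""
    rows = [
        {"regulator": r.regulator, "target": r.target, "mode": r.mode}
        for r in records
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "mode"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    term_name: str
    genes: set

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError("empty gene set")


class GeneSetCollection(dict):
    """Mapping term_id -> GeneSet with unique term ids."""

    def add(self, term_id: str, term_name: str, genes: Iterable[str]) -> None:
        if term_id in self:
            raise FormatError(f"duplicate term id {term_id!r}")
        self[term_id] = GeneSet(term_name, set(genes))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            term_id, term_name, *genes = fields
            coll.add(term_id.strip(), term_name.strip(), {g.strip() for g in genes if g.strip()})
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in coll:
            gs = coll[term_id]
            fh.write("\t".join([term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# physical interaction pairs (STRING-like)
# ---------------------------------------------------------------------------


def read_physical_pairs(
    path: str | Path, min_score: float | None = None
) -> set[frozenset]:
    """Read a STRING-like pair table into a set of unordered pairs.

    Columns: protein_a, protein_b, combined_score (score optional per row).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("protein_a", "protein_b") if c not in df.columns]
    if missing:
        raise FormatError(f"physical pair table lacks column(s): {missing}")
    pairs: set[frozenset] = set()
    for _, row in df.iterrows():
        if min_score is not None and "combined_score" in df.columns:
            try:
                if float(row["combined_score"]) < min_score:
                    continue
            except (TypeError, ValueError):
                continue
        a, b = str(row["protein_a"]).strip(), str(row["protein_b"]).strip()
        if a and b:
            pairs.add(frozenset({a, b}))
    return pairs


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table with columns animal_id, group, gene, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "group": str, "gene": str})
    missing = [c for c in ("animal_id", "group", "gene", "ct") if c not in df.columns]
    if missing:
        raise FormatError(f"qPCR table lacks column(s): {missing}")
    bad = set(df["group"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"qPCR group must be one of {CONDITIONS}, got {sorted(bad)}")
    if df.duplicated(subset=["animal_id", "gene"]).any():
        row = df[df.duplicated(subset=["animal_id", "gene"])].iloc[0]
        raise FormatError(
            f"duplicate Ct for animal {row['animal_id']!r}, gene {row['gene']!r}"
        )
    df["ct"] = df["ct"].astype(float)
    return df


# ---------------------------------------------------------------------------
# GraphML export
# ---------------------------------------------------------------------------


def write_network_graphml(
    net,
    path: str | Path,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Export a RegulatoryNetwork as GraphML with optional node annotations.

    ``node_attrs`` maps node id -> {attribute: value}; annotations for ids
    absent from the network are skipped with a warning. Typical attributes
    are is_DE, direction and is_master_regulator.
    """
    import networkx as nx

    g = net.graph.copy()
    for _, _, data in g.edges(data=True):
        if "sources" in data:
            data["sources"] = "|".join(sorted(data["sources"]))
        if data.get("confidence") is None:
            data.pop("confidence", None)
    if node_attrs:
        for node, attrs in node_attrs.items():
            if node not in g:
                warnings.warn(
                    f"annotation for unknown node {node!r} skipped", stacklevel=2
                )
                continue
            for key, value in attrs.items():
                g.nodes[node][key] = value
    nx.write_graphml(g, str(path))
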