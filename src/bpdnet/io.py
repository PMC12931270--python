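"""Core domain types and readers/writers for count tables, taxonomy, metadata and graphs.

The pipeline's universal currency is the :class:`CountTable`, a samples x taxa
matrix of non-negative integer read counts (ASV abundances).  Taxonomy carries a
six-rank lineage per taxon, sample metadata carries the ordinal disease grade
plus clinical covariates, and :class:`CoNetwork` wraps the thresholded
co-occurrence graph.  All on-disk formats are plain text: TSV tables, GraphML,
and a three-column edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Ordered disease-severity levels: no BPD, then grades I-III.
GROUP_LEVELS = ("non", "I", "II", "III")

#: Taxonomic ranks stored for each ASV, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """A table or graph violates a documented contract."""


class ParseError(ValueError):
    """A file could not be parsed into the expected tabular shape."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    sample_ids, taxon_ids
        Unique row / column identifiers.
    counts
        2-D integer array, shape ``(n_samples, n_taxa)``.
    """

    sample_ids: list
    taxon_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.taxon_ids = list(map(str, self.taxon_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return CountTable(list(ids), list(self.taxon_ids), self.counts[idx, :])

    def select_taxa(self, ids) -> "CountTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in ids]
        return CountTable(list(self.sample_ids), list(ids), self.counts[:, idx])


@dataclass
class TaxonomyTable:
    """Per-taxon ranked lineage (domain..genus); missing ranks are empty strings."""

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages.copy()
        for r in RANKS:
            if r not in df.columns:
                df[r] = ""
        df = df[list(RANKS)].fillna("").astype(str)
        _check_unique(df.index, "taxon")
        self.lineages = df

    @classmethod
    def from_dict(cls, d: dict) -> "TaxonomyTable":
        """Build from ``taxon_id -> sequence of rank names`` (length <= 6)."""
        rows = {}
        for tid, lin in d.items():
            lin = list(lin)
            if len(lin) > len(RANKS):
                raise ValidationError(f"lineage for {tid!r} longer than {len(RANKS)} ranks")
            rows[str(tid)] = lin + [""] * (len(RANKS) - len(lin))
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))

    def lineage(self, taxon_id: str) -> tuple:
        if taxon_id not in self.lineages.index:
            raise ValidationError(f"taxon {taxon_id!r} missing from taxonomy")
        return tuple(self.lineages.loc[taxon_id])

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages.index


@dataclass
class SampleMetadata:
    """Per-sample ordinal group label plus clinical covariates.

    ``table`` is indexed by sample id; the ``group`` column is an ordered
    categorical over :data:`GROUP_LEVELS`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "group" not in df.columns:
            raise ValidationError("metadata must contain a 'group' column")
        bad = set(df["group"].astype(str)) - set(GROUP_LEVELS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        df["group"] = pd.Categorical(
            df["group"].astype(str), categories=list(GROUP_LEVELS), ordered=True
        )
        _check_unique(df.index, "sample")
        self.table = df

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in_group(self, group: str) -> list:
        return list(self.table.index[self.table["group"] == group])

    def group_sizes(self) -> dict:
        return {g: len(self.samples_in_group(g)) for g in GROUP_LEVELS}

    def grade_rank(self) -> pd.Series:
        """Numeric severity rank 0..3 aligned with GROUP_LEVELS order."""
        return self.table["group"].cat.codes.astype(int)


@dataclass
class CoNetwork:
    """Undirected co-occurrence graph of taxa with signed correlation weights.

    Nodes carry a ``relative_abundance`` attribute; edges carry ``r``.  Every
    edge satisfies ``|r| > threshold`` and ``r`` lies in [-1, 1].
    """

    graph: nx.Graph
    threshold: float
    group: str = ""

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges()):
            raise ValidationError("self-loops are not allowed")
        for u, v, d in g.edges(data=True):
            r = d.get("r")
            if r is None:
                raise ValidationError(f"edge ({u}, {v}) missing weight 'r'")
            if not -1.0 <= r <= 1.0:
                raise ValidationError(f"edge ({u}, {v}) weight {r} outside [-1, 1]")
            if abs(r) <= self.threshold:
                raise ValidationError(
                    f"edge ({u}, {v}) |r|={abs(r):.4f} does not exceed threshold "
                    f"{self.threshold}"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set:
        return {frozenset((u, v)) for u, v in self.graph.edges()}


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.; keep line info
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def read_count_table(path, orientation: str = "samples_as_rows") -> CountTable:
    """Read a TSV count table.

    ``orientation`` says what the file's rows are: ``samples_as_rows`` or
    ``taxa_as_rows`` (the BIOM-style TSV convention).  Internally the table is
    always samples x taxa.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry in count table ({exc})") from exc
    if np.any(values != np.floor(values)):
        raise ValidationError(f"{path}: non-integer count entry")
    if orientation == "taxa_as_rows":
        return CountTable(list(df.columns), list(df.index), values.T)
    return CountTable(list(df.index), list(df.columns), values)


def write_count_table(table: CountTable, path, orientation: str = "samples_as_rows") -> None:
    df = table.to_frame()
    if orientation == "taxa_as_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable(_read_tsv(path))


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.lineages.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    for col in df.columns:
        if col == "group":
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        # keep text columns (e.g. delivery mode) as-is
        if not (numeric.isna() & df[col].notna()).any():
            df[col] = numeric
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "edge_list_tsv")


def write_network(net: CoNetwork, path, format: str = "graphml") -> None:
    """Write a co-occurrence network; round-trips node/edge sets and r to 6 d.p."""
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported formats: {', '.join(NETWORK_FORMATS)}"
        )
    if format == "graphml":
        g = net.graph.copy()
        g.graph["threshold"] = float(net.threshold)
        g.graph["group"] = net.group
        for _, _, d in g.edges(data=True):
            d["r"] = round(float(d["r"]), 6)
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("taxon_a\ttaxon_b\tr\n")
            for u, v, d in sorted(net.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['r']:.6f}\n")


def read_network(path, format: str = "graphml", threshold: float = 0.0,
                 group: str = "") -> CoNetwork:
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported formats: {', '.join(NETWORK_FORMATS)}"
        )
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, str)
        thr = float(g.graph.pop("threshold", threshold))
        grp = str(g.graph.pop("group", group))
        clean = nx.Graph()
        clean.add_nodes_from(g.nodes(data=True))
        for u, v, d in g.edges(data=True):
            clean.add_edge(u, v, r=float(d["r"]))
        return CoNetwork(clean, threshold=thr, group=grp)
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", dtype={"taxon_a": str, "taxon_b": str})
    for _, row in df.iterrows():
        g.add_edge(row["taxon_a"], row["taxon_b"], r=float(row["r"]))
    return CoNetwork(g, threshold=threshold, group=group)
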