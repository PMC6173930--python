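"""Readers and writers for the package's plain-text formats.

Formats (all TSV unless stated):

* expression matrix — first column gene id, header row of sample ids;
* sample metadata — ``sample_id, species, age_label, age_order, platform,
  replicate_group``;
* ortholog map — two columns ``gene_a, gene_b``;
* annotated Newick — standard Newick with internal-node labels ``AU|BP``
  given as percentages and branch lengths equal to merge-height
  differences.

Readers reject malformed input rather than coercing it; gene identifiers
are upper-cased before any join so symbol matching across sources is
case-insensitive.  Lines starting with ``#`` are treated as comments.
"""
from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo

from .cluster import CladeSupport, ClusterTree
from .errors import DataError
from .matrix import META_COLUMNS, ExpressionMatrix, OrthologMap

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------
def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in meta.columns:
        raise DataError(f"{path}: metadata must have a 'sample_id' column")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"{path}: duplicate sample_id(s) {dups}")
    meta = meta.set_index("sample_id")
    meta["age_order"] = meta["age_order"].astype(int)
    return meta


def read_expression_tsv(
    path, metadata_path, scale: str = "raw", impute_missing: bool = False
) -> ExpressionMatrix:
    """Load an expression TSV joined with its sample metadata.

    Duplicate gene rows are collapsed by per-sample mean (logged); missing
    cells are rejected unless ``impute_missing`` asks for per-gene mean
    imputation.  All-zero rows are retained — filtering is an explicit
    downstream step.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.upper()
    raw.index.name = "gene_id"
    meta = read_sample_metadata(metadata_path)
    for sample in raw.columns:
        if sample not in meta.index:
            raise DataError(f"{path}: sample {sample!r} absent from metadata {metadata_path}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise DataError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        values[col] = converted
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        log.warning("%s: collapsing duplicate gene rows by mean: %s", path, dups)
        values = values.groupby(level=0, sort=False).mean()
    if values.isna().any().any():
        if not impute_missing:
            i, j = np.argwhere(values.isna().to_numpy())[0]
            raise DataError(
                f"{path}: missing value at gene {values.index[i]!r}, "
                f"sample {values.columns[j]!r} (set impute_missing to allow)"
            )
        row_means = values.mean(axis=1)
        if row_means.isna().any():
            raise DataError(f"{path}: gene(s) with all values missing cannot be imputed")
        values = values.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values, meta=meta, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path, metadata_path=None, header: str = ""):
    """Write matrix (and optionally its metadata) back to TSV.

    ``header`` lines are emitted as ``#`` comments so outputs are
    self-describing and still round-trip through the readers.
    """
    path = Path(path)
    with path.open("w") as fh:
        for line in filter(None, header.split("\n")):
            fh.write(f"# {line}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        matrix.meta.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------
def read_ortholog_map(path) -> OrthologMap:
    """Two-column TSV -> one-to-one map.

    Any identifier participating in more than one pair is dropped entirely
    (with a logged count); an empty file is an error, an empty map after
    the one-to-one rule is not.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] != 2:
        raise DataError(f"{path}: ortholog map must have exactly two columns")
    if df.shape[0] == 0:
        raise DataError(f"{path}: ortholog map is empty")
    pairs = [(str(a).upper(), str(b).upper()) for a, b in df.itertuples(index=False)]
    omap = OrthologMap.one_to_one(pairs)
    n_dropped = len(pairs) - len(omap)
    if n_dropped:
        log.warning("%s: dropped %d ambiguous ortholog pair(s)", path, n_dropped)
    return omap


def write_ortholog_map(omap: OrthologMap, path) -> None:
    pd.DataFrame(omap.pairs, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotated Newick
# ---------------------------------------------------------------------------
def _support_label(sup: CladeSupport | None) -> str:
    if sup is None:
        return ""
    return f"{round(sup.au * 100, 1):g}|{round(sup.bp * 100, 1):g}"


def write_newick_annotated(tree: ClusterTree, path) -> None:
    """Serialise a dendrogram to Newick with ``AU|BP`` internal labels.

    Branch lengths are merge-height differences (leaves sit at height 0),
    so an ultrametric tree round-trips exactly through
    :func:`read_newick_annotated`.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (i, j, h) in enumerate(tree.merges):
        node = n + k
        heights[node] = float(h)
        children[node] = (int(i), int(j))

    def render(node: int, parent_height: float) -> str:
        blen = parent_height - heights[node]
        if node < n:
            label = str(tree.leaves[node])
            if any(ch in label for ch in "(),:;|"):
                raise DataError(f"leaf label {label!r} contains Newick-reserved characters")
            return f"{label}:{blen!r}"
        a, b = children[node]
        sup = tree.support.get(node - n)
        inner = f"({render(a, heights[node])},{render(b, heights[node])}){_support_label(sup)}"
        if node == 2 * n - 2:  # root carries no branch length
            return inner
        return f"{inner}:{blen!r}"

    Path(path).write_text(render(2 * n - 2, heights[2 * n - 2]) + ";\n")


def read_newick_annotated(path) -> ClusterTree:
    """Parse an annotated Newick file back into a :class:`ClusterTree`.

    The tree must be binary and ultrametric (as written by
    :func:`write_newick_annotated`); internal labels of the form ``AU|BP``
    (percentages) are restored into per-node support.
    """
    text = Path(path).read_text()
    phylo = Phylo.read(_stdio.StringIO(text), "newick")
    root = phylo.root

    depths: dict = {}

    def set_depth(clade, d):
        depths[id(clade)] = d
        for ch in clade.clades:
            set_depth(ch, d + (ch.branch_length or 0.0))

    set_depth(root, 0.0)
    max_depth = max(depths[id(t)] for t in phylo.get_terminals())

    leaves: list[str] = []
    internal: list[tuple[float, list[int], object]] = []  # (height, child slots, clade)

    def walk(clade) -> dict:
        if not clade.clades:
            if clade.name is None:
                raise DataError("unlabeled leaf in Newick input")
            leaves.append(str(clade.name))
            return {"leaf": len(leaves) - 1, "clade": clade}
        if len(clade.clades) != 2:
            raise DataError("annotated Newick trees must be binary")
        kids = [walk(ch) for ch in clade.clades]
        node = {"children": kids, "clade": clade, "height": max_depth - depths[id(clade)]}
        return node

    tree_struct = walk(root)

    nodes: list[dict] = []

    def collect(node):
        if "leaf" in node:
            return
        for ch in node["children"]:
            collect(ch)
        nodes.append(node)

    collect(tree_struct)
    nodes.sort(key=lambda nd: nd["height"])
    n = len(leaves)
    ids: dict[int, int] = {}
    merges = np.zeros((n - 1, 3))
    support: dict[int, CladeSupport] = {}
    for k, node in enumerate(nodes):
        child_ids = []
        for ch in node["children"]:
            child_ids.append(ch["leaf"] if "leaf" in ch else ids[id(ch)])
        ids[id(node)] = n + k
        merges[k] = [child_ids[0], child_ids[1], node["height"]]
        label = node["clade"].name
        if label is None and node["clade"].confidence is not None:
            label = str(node["clade"].confidence)
        if label and "|" in str(label):
            au_s, bp_s = str(label).split("|", 1)
            support[k] = CladeSupport(bp=float(bp_s) / 100.0, au=float(au_s) / 100.0)
    return ClusterTree(leaves=leaves, merges=merges, support=support)
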