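"""Readers and writers for the pipeline's on-disk formats.

Conventions: expression matrices are genes-as-rows, TSV with a header row of
sample ids (or MTX triplet plus ``genes.tsv``/``barcodes.tsv`` sidecars);
sample metadata is a sidecar TSV; gene sets are GMT; cohorts, DEG tables,
edge lists and ortholog maps are TSV.  All writers round-trip losslessly at 6
significant digits.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sparse

from .coregnet import CoregNetwork
from .diffexp import ExpressionMatrix
from .signatures import GeneSet, OrthologMap
from .synth import SurvivalCohort

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_cohort",
    "write_cohort",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_network",
    "write_network",
]


def _read_meta(meta_path: Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "population" not in meta.columns:
        raise ValueError(f"{meta_path}: metadata lacks a 'population' column")
    return meta


def read_matrix(
    path: str | Path, meta_path: str | Path, fmt: str = "tsv", scale: str = "count"
) -> ExpressionMatrix:
    """Load a genes-by-samples matrix (TSV dense or MTX triplet) + metadata.

    For ``fmt='mtx'`` the path is the ``.mtx`` file and ``genes.tsv`` /
    ``barcodes.tsv`` sidecars are expected next to it (one id per line).
    Duplicate gene ids are rejected.
    """
    path = Path(path)
    if fmt == "tsv":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicated gene row(s): {dup[:5]}")
    elif fmt == "mtx":
        mat = spio.mmread(path)
        genes = Path(path).with_name("genes.tsv").read_text().split()
        barcodes = Path(path).with_name("barcodes.tsv").read_text().split()
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"{path}: MTX is {mat.shape[0]}x{mat.shape[1]} but sidecars name "
                f"{len(genes)} genes and {len(barcodes)} samples"
            )
        values = pd.DataFrame(np.asarray(mat.todense()), index=genes, columns=barcodes)
        if values.index.duplicated().any():
            raise ValueError(f"{path}: duplicated gene id in genes.tsv")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return ExpressionMatrix(values, _read_meta(Path(meta_path)), scale=scale)


def write_matrix(
    mat: ExpressionMatrix, path: str | Path, meta_path: str | Path, fmt: str = "tsv"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        out = mat.values if mat.scale == "count" else mat.values.round(6)
        out.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(mat.values.to_numpy()))
        path.with_name("genes.tsv").write_text("\n".join(mat.values.index) + "\n")
        path.with_name("barcodes.tsv").write_text("\n".join(mat.values.columns) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    mat.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>id...``."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (need name, description, >=1 id)")
        name, desc, *ids = parts
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen.add(name)
        if len(set(ids)) != len(ids):
            warnings.warn(f"{path}:{lineno}: duplicate ids in set {name!r} deduplicated", stacklevel=2)
        sets.append(GeneSet(name, frozenset(ids), (desc or "input",)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for s in sets:
        desc = ";".join(s.provenance)
        lines.append("\t".join([s.name, desc, *sorted(s.gene_ids)]))
    path.write_text("\n".join(lines) + "\n")


def read_cohort(path: str | Path) -> SurvivalCohort:
    return SurvivalCohort(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: SurvivalCohort, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Two-column TSV (mouse_id, human_id) -> one-to-one ortholog map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mouse_id, human_id)")
    pairs = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return OrthologMap(pairs, method="provided")


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(sorted(omap.pairs.items()), columns=["mouse_id", "human_id"])
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, m_samples: int) -> CoregNetwork:
    """Edge-list TSV (gene_a, gene_b, r, p) -> network."""
    import networkx as nx

    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        graph.add_edge(str(row.gene_a), str(row.gene_b), r=float(row.r), p=float(row.p))
    return CoregNetwork(graph, m_samples=m_samples)


def write_network(net: CoregNetwork, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    net.edge_table().to_csv(path, sep="\t", index=False, float_format="%.6g")
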