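"""Readers and writers for the platform's tab-separated formats.

All formats are UTF-8 TSV with a mandatory header row, ``NA`` as the
missing-value sentinel and ``#``-prefixed comment lines (used to carry
run provenance such as the config hash).  Readers validate column
contracts and report duplicates by identifier; writers round-trip
losslessly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd

from .cocite import CocitationNetwork
from .domains import ArchitectureTable, DomainArchitecture
from .hippi import FamilyClustering, KnownInteraction, N_LEVELS


def _read_tsv(path_or_buf, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(
        path_or_buf, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    return df


def _check_unique(values: pd.Series, what: str) -> None:
    dup = values[values.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate {what}: {dup.iloc[0]!r}")


def _writer(path_or_buf) -> tuple[TextIO, bool]:
    if isinstance(path_or_buf, (str, Path)):
        return open(path_or_buf, "w", encoding="utf-8"), True
    return path_or_buf, False


def _write_df(df: pd.DataFrame, path_or_buf, header_comment: str | None = None) -> None:
    fh, close = _writer(path_or_buf)
    try:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")
    finally:
        if close:
            fh.close()


# -- edge lists --------------------------------------------------------------

def read_edge_tsv(path_or_buf) -> list[tuple[str, str, str]]:
    df = _read_tsv(path_or_buf, ["p1", "p2", "relation_class"], "edge list")
    return [tuple(r) for r in df[["p1", "p2", "relation_class"]].itertuples(index=False)]


def write_edge_tsv(edges: Iterable[tuple[str, str, str]], path_or_buf, comment=None) -> None:
    df = pd.DataFrame(sorted(edges), columns=["p1", "p2", "relation_class"])
    _write_df(df, path_or_buf, comment)


def read_cocitation_network(path_or_buf) -> CocitationNetwork:
    return CocitationNetwork.from_edges(read_edge_tsv(path_or_buf))


def read_untagged_edges(path_or_buf) -> list[tuple[str, str]]:
    df = _read_tsv(path_or_buf, ["p1", "p2"], "edge list")
    return [tuple(r) for r in df[["p1", "p2"]].itertuples(index=False)]


def write_untagged_edges(edges: Iterable[tuple[str, str]], path_or_buf, comment=None) -> None:
    df = pd.DataFrame(sorted(edges), columns=["p1", "p2"])
    _write_df(df, path_or_buf, comment)


# -- reference sets ----------------------------------------------------------

def read_id_list(path_or_buf) -> list[str]:
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text(encoding="utf-8")
    else:
        text = path_or_buf.read()
    ids = [ln.strip() for ln in text.splitlines()
           if ln.strip() and not ln.startswith("#")]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate identifier {i!r}")
        seen.add(i)
    return ids


def write_id_list(ids: Iterable[str], path_or_buf, comment=None) -> None:
    fh, close = _writer(path_or_buf)
    try:
        if comment:
            fh.write(f"# {comment}\n")
        for i in sorted(ids):
            fh.write(f"{i}\n")
    finally:
        if close:
            fh.close()


# -- domain architectures ----------------------------------------------------

def read_architecture_tsv(path_or_buf) -> ArchitectureTable:
    df = _read_tsv(path_or_buf, ["genome", "protein", "superfamilies"], "architectures")
    _check_unique(df["genome"] + "\t" + df["protein"], "architecture row")
    archs = [
        DomainArchitecture(r.genome, r.protein, tuple(r.superfamilies.split(",")))
        for r in df.itertuples(index=False)
    ]
    return ArchitectureTable.from_architectures(archs)


def write_architecture_tsv(table: ArchitectureTable, path_or_buf, comment=None) -> None:
    rows = [
        {"genome": g, "protein": p, "superfamilies": ",".join(a.superfamilies)}
        for g in sorted(table.by_genome)
        for p, a in sorted(table.by_genome[g].items())
    ]
    _write_df(pd.DataFrame(rows), path_or_buf, comment)


# -- family clustering and known interactions --------------------------------

def read_clustering_tsv(path_or_buf) -> FamilyClustering:
    df = _read_tsv(path_or_buf, ["protein", "family", "levels"], "clustering")
    _check_unique(df["protein"], "protein")
    clustering = FamilyClustering()
    for line_no, r in enumerate(df.itertuples(index=False), start=2):
        ids = r.levels.split(",")
        if len(ids) != N_LEVELS:
            raise ValueError(
                f"clustering line {line_no}: expected {N_LEVELS} cluster IDs"
            )
        clustering.add(r.protein, r.family, ids)
    return clustering


def write_clustering_tsv(clustering: FamilyClustering, path_or_buf, comment=None) -> None:
    rows = [
        {
            "protein": p,
            "family": clustering.family_of[p],
            "levels": ",".join(clustering.levels[p]),
        }
        for p in sorted(clustering.family_of)
    ]
    _write_df(pd.DataFrame(rows), path_or_buf, comment)


def read_known_interactions_tsv(path_or_buf) -> list[KnownInteraction]:
    df = _read_tsv(path_or_buf, ["p1", "p2", "evidence_types", "species"], "interactions")
    return [
        KnownInteraction(
            r.p1,
            r.p2,
            frozenset(r.evidence_types.split(",")),
            frozenset(r.species.split(",")),
        )
        for r in df.itertuples(index=False)
    ]


def write_known_interactions_tsv(
    interactions: Iterable[KnownInteraction], path_or_buf, comment=None
) -> None:
    rows = [
        {
            "p1": k.a,
            "p2": k.b,
            "evidence_types": ",".join(sorted(k.evidence_types)),
            "species": ",".join(sorted(k.species)),
        }
        for k in interactions
    ]
    rows.sort(key=lambda r: (r["p1"], r["p2"]))
    _write_df(pd.DataFrame(rows), path_or_buf, comment)


# -- numeric tables ----------------------------------------------------------

def read_matrix_tsv(path_or_buf, index_name: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", na_values=["NA"])
    if df.columns[0] != index_name:
        raise ValueError(f"expected first column {index_name!r}, got {df.columns[0]!r}")
    _check_unique(df[index_name], index_name)
    return df.set_index(index_name)


def write_matrix_tsv(df: pd.DataFrame, path_or_buf, index_name: str = "gene",
                     comment=None) -> None:
    out = df.copy()
    out.index.name = index_name
    fh, close = _writer(path_or_buf)
    try:
        if comment:
            fh.write(f"# {comment}\n")
        out.to_csv(fh, sep="\t", na_rep="NA", lineterminator="\n")
    finally:
        if close:
            fh.close()


def read_labels_tsv(path_or_buf) -> pd.Series:
    df = _read_tsv(path_or_buf, ["protein", "label"], "labels")
    _check_unique(df["protein"], "protein")
    return pd.Series(
        df["label"].astype(int).to_numpy(), index=df["protein"], name="label"
    )


def write_labels_tsv(labels: pd.Series, path_or_buf, comment=None) -> None:
    df = pd.DataFrame({"protein": labels.index, "label": labels.to_numpy()})
    _write_df(df, path_or_buf, comment)


# -- ontology ----------------------------------------------------------------

def read_dag_tsv(path_or_buf) -> list[tuple[str, str]]:
    df = _read_tsv(path_or_buf, ["child", "parent"], "term DAG")
    return [tuple(r) for r in df[["child", "parent"]].itertuples(index=False)]


def write_dag_tsv(edges: Iterable[tuple[str, str]], path_or_buf, comment=None) -> None:
    _write_df(pd.DataFrame(sorted(edges), columns=["child", "parent"]), path_or_buf, comment)


def read_obo_dag(path: str) -> list[tuple[str, str]]:
    """is-a edges (child, parent) from an OBO file, via obonet."""
    import obonet

    graph = obonet.read_obo(path)
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    return edges


def read_annotations_tsv(path_or_buf) -> dict[str, set[str]]:
    df = _read_tsv(path_or_buf, ["protein", "term"], "annotations")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.protein, set()).add(r.term)
    return out


def write_annotations_tsv(
    annotations: Mapping[str, Iterable[str]], path_or_buf, comment=None
) -> None:
    rows = [
        {"protein": p, "term": t}
        for p in sorted(annotations)
        for t in sorted(annotations[p])
    ]
    _write_df(pd.DataFrame(rows), path_or_buf, comment)


# -- scores, matrices, rankings ----------------------------------------------

def write_scores_tsv(scores: Mapping[str, float], path_or_buf, comment=None) -> None:
    rows = [{"target": t, "score": s} for t, s in sorted(scores.items())]
    _write_df(pd.DataFrame(rows), path_or_buf, comment)


def read_scores_tsv(path_or_buf) -> dict[str, float]:
    df = _read_tsv(path_or_buf, ["target", "score"], "scores")
    _check_unique(df["target"], "target")
    return {r.target: float(r.score) for r in df.itertuples(index=False)}


def write_ranking_tsv(table: pd.DataFrame, path_or_buf, comment=None) -> None:
    _write_df(table, path_or_buf, comment)


def read_ranking_tsv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", na_values=["NA"])
    for col in ("rank", "target", "p_spip"):
        if col not in df.columns:
            raise ValueError(f"ranking file missing column {col!r}")
    return df


def serialize(write_fn, obj, **kwargs) -> str:
    """Render any writer's output as a string (used for content hashing)."""
    buf = _io.StringIO()
    write_fn(obj, buf, **kwargs)
    return buf.getvalue()
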