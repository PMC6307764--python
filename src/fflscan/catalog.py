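"""Directed regulatory interactions and candidate feed-forward loop enumeration.

Four curated edge sets are held: miRNA->gene, miRNA->TF, TF->gene and
TF->miRNA.  A candidate three-node feed-forward loop (FFL) couples a miRNA
and a TF that regulate each other (in at least one direction) with a gene
targeted by both.  Loops are typed by the master regulator:

* miRNA-FFL — miRNA->TF, miRNA->gene, TF->gene (3 edges)
* TF-FFL — TF->miRNA, TF->gene, miRNA->gene (3 edges)
* composite-FFL — mutual miRNA<->TF regulation plus both target edges (4 edges)

Composite takes precedence when both regulator edges exist, which makes the
three classes a disjoint partition of the candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .expression import ExpressionStudy

log = logging.getLogger(__name__)

EDGE_TYPES = ("mirna_gene", "mirna_tf", "tf_gene", "tf_mirna")
FFL_TYPES = ("miRNA-FFL", "TF-FFL", "composite-FFL")

#: class of (regulator, target) per edge type
_EDGE_CLASSES = {
    "mirna_gene": ("miRNA", "gene"),
    "mirna_tf": ("miRNA", "TF"),
    "tf_gene": ("TF", "gene"),
    "tf_mirna": ("TF", "miRNA"),
}


class CatalogError(ValueError):
    """Raised for malformed interaction input."""


@dataclass(frozen=True)
class FFL:
    """A typed (miRNA, TF, gene) feed-forward loop."""

    mirna: str
    tf: str
    gene: str
    ffl_type: str

    def __post_init__(self) -> None:
        if self.ffl_type not in FFL_TYPES:
            raise CatalogError(f"unknown FFL type {self.ffl_type!r}")
        if self.gene in (self.mirna, self.tf):
            raise CatalogError(f"gene {self.gene!r} collides with a regulator")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mirna, self.tf, self.gene)

    @property
    def n_edges(self) -> int:
        return 4 if self.ffl_type == "composite-FFL" else 3

    @property
    def edges(self) -> frozenset[tuple[str, str, str]]:
        """Typed directed links as (regulator, target, edge_type)."""
        e = {(self.mirna, self.gene, "mirna_gene"), (self.tf, self.gene, "tf_gene")}
        if self.ffl_type in ("miRNA-FFL", "composite-FFL"):
            e.add((self.mirna, self.tf, "mirna_tf"))
        if self.ffl_type in ("TF-FFL", "composite-FFL"):
            e.add((self.tf, self.mirna, "tf_mirna"))
        return frozenset(e)

    @property
    def pairs(self) -> set[frozenset[str]]:
        """Unordered co-expression pairs spanned by the loop (always 3)."""
        return {
            frozenset((self.mirna, self.tf)),
            frozenset((self.mirna, self.gene)),
            frozenset((self.tf, self.gene)),
        }


@dataclass
class InteractionCatalog:
    """Deduplicated directed regulation pairs, one set per edge type."""

    mirna_gene: set[tuple[str, str]] = field(default_factory=set)
    mirna_tf: set[tuple[str, str]] = field(default_factory=set)
    tf_gene: set[tuple[str, str]] = field(default_factory=set)
    tf_mirna: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for et in EDGE_TYPES:
            pairs = getattr(self, et)
            selfpairs = {p for p in pairs if p[0] == p[1]}
            if selfpairs:
                log.warning("dropping %d self-pairs from %s", len(selfpairs), et)
                setattr(self, et, set(pairs) - selfpairs)

    def pair_counts(self) -> dict[str, int]:
        return {et: len(getattr(self, et)) for et in EDGE_TYPES}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionCatalog):
            return NotImplemented
        return all(getattr(self, et) == getattr(other, et) for et in EDGE_TYPES)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_catalog(path: str | Path) -> InteractionCatalog:
    """Read a catalog TSV with columns regulator, target, edge_type.

    Duplicate lines collapse to one pair (set semantics); an unknown
    edge_type is a hard error naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("regulator", "target", "edge_type"):
        if col not in df.columns:
            raise CatalogError(f"{path}: missing column {col!r}")
    sets: dict[str, set[tuple[str, str]]] = {et: set() for et in EDGE_TYPES}
    for i, (reg, tgt, et) in enumerate(
        zip(df["regulator"], df["target"], df["edge_type"]), start=2
    ):
        if et not in sets:
            raise CatalogError(f"{path}: unknown edge_type {et!r} at line {i}")
        sets[et].add((str(reg), str(tgt)))
    return InteractionCatalog(**sets)


def write_catalog(catalog: InteractionCatalog, path: str | Path) -> None:
    rows = [
        (reg, tgt, et)
        for et in EDGE_TYPES
        for reg, tgt in sorted(getattr(catalog, et))
    ]
    pd.DataFrame(rows, columns=["regulator", "target", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Restriction and enumeration
# ---------------------------------------------------------------------------

def restrict_to_profiled(
    catalog: InteractionCatalog, study: ExpressionStudy
) -> InteractionCatalog:
    """Keep only pairs whose endpoints are measured with the declared class."""
    kept: dict[str, set[tuple[str, str]]] = {}
    for et in EDGE_TYPES:
        reg_cls, tgt_cls = _EDGE_CLASSES[et]
        pairs = getattr(catalog, et)
        keep = {
            (a, b)
            for a, b in pairs
            if study.feature_class.get(a) == reg_cls
            and study.feature_class.get(b) == tgt_cls
        }
        if len(keep) != len(pairs):
            log.info("%s: dropped %d of %d unprofiled pairs", et, len(pairs) - len(keep), len(pairs))
        kept[et] = keep
    return InteractionCatalog(**kept)


def enumerate_ffls(catalog: InteractionCatalog) -> list[FFL]:
    """Enumerate candidate FFLs, one per (miRNA, TF, gene) triple.

    A triple qualifies when the miRNA and TF are linked in at least one
    direction and both target the gene.  Type precedence: composite if both
    miRNA->TF and TF->miRNA exist, else miRNA-FFL, else TF-FFL.  Output is
    sorted by (miRNA, TF, gene).
    """
    mg: dict[str, set[str]] = {}
    for m, g in catalog.mirna_gene:
        mg.setdefault(m, set()).add(g)
    tg: dict[str, set[str]] = {}
    for t, g in catalog.tf_gene:
        tg.setdefault(t, set()).add(g)
    mt_pairs = set(catalog.mirna_tf)
    tm_pairs = {(m, t) for t, m in catalog.tf_mirna}

    out: list[FFL] = []
    for m, t in mt_pairs | tm_pairs:
        common = mg.get(m, set()) & tg.get(t, set())
        if not common:
            continue
        if (m, t) in mt_pairs and (m, t) in tm_pairs:
            ftype = "composite-FFL"
        elif (m, t) in mt_pairs:
            ftype = "miRNA-FFL"
        else:
            ftype = "TF-FFL"
        for g in common:
            if g in (m, t):
                continue
            out.append(FFL(mirna=m, tf=t, gene=g, ffl_type=ftype))
    out.sort(key=lambda f: f.key)
    return out


def ffl_table(ffls: Iterable[FFL]) -> pd.DataFrame:
    """Tabulate loops with columns mirna, tf, gene, ffl_type, n_edges."""
    return pd.DataFrame(
        [(f.mirna, f.tf, f.gene, f.ffl_type, f.n_edges) for f in ffls],
        columns=["mirna", "tf", "gene", "ffl_type", "n_edges"],
    )
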