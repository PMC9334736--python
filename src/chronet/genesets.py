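"""Gene sets and undirected edge lists: containers and plain-text readers."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GeneSet", "EdgeList", "read_gene_set", "read_gene_sets", "read_edge_list"]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers (duplicates removed on load)."""

    label: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EdgeList:
    """Undirected gene-pair edges with canonical (sorted-tuple) identity."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        self.pairs.add(self.canonical(a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.canonical(*pair) in self.pairs

    def nodes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def restrict_to(self, genes) -> tuple["EdgeList", int]:
        """Keep edges whose both endpoints are in ``genes``; report drops."""
        genes = set(genes)
        kept = {p for p in self.pairs if p[0] in genes and p[1] in genes}
        return EdgeList(kept), len(self.pairs) - len(kept)


def read_gene_set(path, label: str | None = None) -> GeneSet:
    """One identifier per line; ``#`` starts a comment."""
    genes = []
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                genes.append(token)
    return GeneSet(label or str(path), frozenset(genes))


def read_gene_sets(path) -> list[GeneSet]:
    """Two-column TSV (set_label, gene) holding many sets."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["label", "gene"], dtype=str)
    return [
        GeneSet(label, frozenset(sub["gene"]))
        for label, sub in frame.groupby("label", sort=True)
    ]


def read_edge_list(path) -> EdgeList:
    """Two-column TSV of undirected edges; optional header; self-loops rejected."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"edge list {path} needs two columns")
    edges = EdgeList()
    rows = frame.iloc[:, :2].itertuples(index=False)
    first = True
    for a, b in rows:
        if first and {str(a).lower(), str(b).lower()} & {"source", "target", "gene_a", "gene_b"}:
            first = False
            continue  # header row
        first = False
        edges.add(str(a), str(b))
    return edges
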