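"""Strain phylogeny container.

Newick parsing/writing is delegated to dendropy; internally the tree is held
as flat preorder arrays (parent pointers, child lists, edge lengths) that the
parsimony dynamic programs and the continuous reconstruction index directly.
The root is node 0 and every parent precedes its children, so a forward scan
is a preorder traversal and a reverse scan is a postorder traversal.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

__all__ = ["StrainTree"]


class StrainTree:
    """A strain phylogeny with tip labels and branch lengths.

    Parameters
    ----------
    parent
        ``parent[v]`` is the parent node id of ``v`` (``-1`` for the root).
        Nodes must be numbered in preorder: ``parent[v] < v`` for ``v > 0``.
    children
        ``children[v]`` lists the child node ids of ``v`` in order.
    edge_length
        Length of the branch above each node; ``nan`` marks an unspecified
        length (newick without branch lengths). The root entry is ignored.
    labels
        Per-node label; tips must be labelled, internal labels are optional
        (``None`` when absent). Labels are stripped of surrounding
        whitespace and must be unique across tips.

    Polytomies and zero-length branches are allowed. Branch lengths are in
    arbitrary units; only products with gain/loss rates and length ratios
    are ever interpreted.
    """

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        edge_length: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = [
            lbl.strip() if isinstance(lbl, str) else None for lbl in labels
        ]
        self._validate()
        self.tip_nodes = np.array(
            [v for v in range(self.n_nodes) if not self.children[v]],
            dtype=np.int64,
        )
        self.tip_labels: list[str] = [self.labels[v] for v in self.tip_nodes]
        self.tip_index: dict[str, int] = {
            lbl: int(v) for lbl, v in zip(self.tip_labels, self.tip_nodes)
        }

    # ------------------------------------------------------------------
    # construction / serialisation

    @classmethod
    def from_newick(cls, newick: str) -> "StrainTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            if "Multiple occurrences" in str(exc):
                raise ValueError(f"duplicate tip label in newick: {exc}") from exc
            raise ValueError(f"invalid newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "StrainTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in nodes]
        lengths = np.full(len(nodes), np.nan)
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
            if nd.edge.length is not None:
                lengths[i] = nd.edge.length
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
        return cls(parent, children, lengths, labels)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            name = self.labels[v] or ""
            if self.children[v]:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")" + name
            else:
                s = name
            if self.parent[v] >= 0 and not np.isnan(self.edge_length[v]):
                s += ":" + repr(float(self.edge_length[v]))
            return s

        return fmt(0) + ";"

    # ------------------------------------------------------------------
    # basic queries

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_nodes)

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def preorder(self) -> Iterator[int]:
        return iter(range(self.n_nodes))

    def postorder(self) -> Iterator[int]:
        return iter(range(self.n_nodes - 1, -1, -1))

    def edges(self) -> np.ndarray:
        """Node ids of edge children (every node but the root)."""
        return np.arange(1, self.n_nodes, dtype=np.int64)

    def resolved_lengths(
        self, default: float = 1.0, zero_eps: float | None = None
    ) -> np.ndarray:
        """Branch lengths with unspecified lengths replaced by ``default``.

        When ``zero_eps`` is given, zero lengths are lifted to that value
        (used by the continuous reconstruction, which divides by length).
        The root entry is set to 0.
        """
        out = np.where(np.isnan(self.edge_length), default, self.edge_length)
        if zero_eps is not None:
            out = np.where(out <= 0.0, zero_eps, out)
        out = out.copy()
        out[0] = 0.0
        return out

    def depth(self) -> float:
        """Maximum root-to-tip path length (unspecified lengths count 1)."""
        ln = self.resolved_lengths()
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + ln[v]
        return float(d[self.tip_nodes].max()) if self.n_tips else 0.0

    def tip_values(self, mapping: Mapping[str, float]) -> np.ndarray:
        """Values for every tip, ordered like ``tip_nodes``.

        Raises ``KeyError``-derived ``ValueError`` when a tip is missing.
        """
        try:
            return np.array([mapping[lbl] for lbl in self.tip_labels], dtype=float)
        except KeyError as exc:
            raise ValueError(f"no value supplied for tip {exc.args[0]!r}") from exc

    def prune_to(self, labels: Iterable[str]) -> "StrainTree":
        """Tree restricted to the given tip labels (unifurcations merged)."""
        keep = set(labels)
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise ValueError(f"labels not in tree: {sorted(unknown)}")
        if keep == set(self.tip_labels):
            return self
        if len(keep) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        dtree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        dtree.retain_taxa_with_labels(sorted(keep))
        return StrainTree.from_dendropy(dtree)

    # ------------------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise ValueError("empty tree")
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the root")
        for v in range(1, n):
            if not 0 <= self.parent[v] < v:
                raise ValueError("nodes must be numbered in preorder")
        with np.errstate(invalid="ignore"):
            if np.any(self.edge_length[1:] < 0):
                raise ValueError("negative branch length")
        tips = [v for v in range(n) if not self.children[v]]
        tip_labels = [self.labels[v] for v in tips]
        if any(lbl is None or lbl == "" for lbl in tip_labels):
            raise ValueError("every tip must be labelled")
        seen: set[str] = set()
        for lbl in tip_labels:
            if lbl in seen:
                raise ValueError(f"duplicate tip label {lbl!r}")
            seen.add(lbl)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<StrainTree n_tips={self.n_tips} n_nodes={self.n_nodes}>"
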