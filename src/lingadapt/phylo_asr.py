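"""Continuous ancestral-state reconstruction and phylomorphospace coordinates.

For a historical case study, trait values observed at the tips of a phylogeny
(for instance tone count and ambient humidity of attested languages) are
projected back onto the internal nodes under a Brownian-motion model.  The
maximum-likelihood ancestral states under Brownian motion are the node values
minimising the sum over edges of (x_parent - x_child)^2 / branch length
(weighted squared-change parsimony), a sparse linear system solved exactly.
A phylomorphospace layout places every node in a two-trait plane with edges
mirroring the tree topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "AncestralEstimates",
    "read_newick",
    "write_newick",
    "asr_brownian",
    "phylomorpho_layout",
]

ASR_METHOD_TAG = "ml-brownian (weighted squared-change parsimony)"


@dataclass
class Phylogeny:
    """A rooted tree with uniquely labeled tips; missing branch lengths are
    treated as unit length."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.head_node.parent_node is not None:
                if edge.length <= 0:
                    raise ValueError("branch lengths must be > 0 where given")
        self._name_nodes()

    def _name_nodes(self) -> None:
        k = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"anc{k}"
            k += 1

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def internal_labels(self) -> list[str]:
        return [n.label for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_internal(self) -> int:
        return len(self.internal_labels)

    def edges(self) -> list[tuple[str, str, float]]:
        """(parent label, child label, branch length) with unit default."""
        out = []
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            child = node.taxon.label if node.is_leaf() else node.label
            par = parent.taxon.label if parent.is_leaf() else parent.label
            length = node.edge.length if node.edge.length is not None else 1.0
            out.append((par, child, float(length)))
        return out


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Malformed input raises a ValueError carrying the parser's position
    report.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    # dendropy stores internal labels as taxa when suppress_..=False; move to .label
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.taxon is not None:
            node.label = node.taxon.label
            node.taxon = None
    return Phylogeny(tree)


def write_newick(phylo: Phylogeny) -> str:
    return phylo.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class AncestralEstimates:
    """Estimated trait values at every internal node."""

    estimates: pd.DataFrame  # index internal node label, one column per trait
    method: str = ASR_METHOD_TAG


def _trait_frame(tip_values) -> pd.DataFrame:
    if isinstance(tip_values, pd.DataFrame):
        return tip_values.astype(float)
    return pd.DataFrame({"trait": pd.Series(dict(tip_values), dtype=float)})


def asr_brownian(phylo: Phylogeny, tip_values) -> AncestralEstimates:
    """Maximum-likelihood ancestral states under Brownian motion.

    ``tip_values`` maps tip label -> value (or a DataFrame indexed by tip
    label with one column per trait).  Every tip needs a value; a missing tip
    is reported by name.  The estimates solve the weighted-Laplacian linear
    system in which each edge contributes weight 1 / branch length, so they
    are linear in the tip values, lie within the tip range, and are invariant
    to rescaling all branch lengths.
    """
    traits = _trait_frame(tip_values)
    tips = phylo.tip_labels
    missing = [t for t in tips if t not in traits.index]
    if missing:
        raise ValueError(f"missing tip value for {missing[0]!r}")
    internal = phylo.internal_labels
    idx = {label: i for i, label in enumerate(internal)}

    q = len(internal)
    A = np.zeros((q, q))
    C = np.zeros((q, traits.shape[1]))
    for parent, child, length in phylo.edges():
        w = 1.0 / length
        i = idx[parent]
        if child in idx:  # internal-internal edge
            j = idx[child]
            A[i, i] += w
            A[j, j] += w
            A[i, j] -= w
            A[j, i] -= w
        else:  # internal-tip edge
            A[i, i] += w
            C[i, :] += w * traits.loc[child].to_numpy()
    est = np.linalg.solve(A, C)
    if not np.isfinite(est).all():
        raise ValueError("ancestral estimates are not finite")
    frame = pd.DataFrame(est, index=internal, columns=traits.columns)
    return AncestralEstimates(estimates=frame)


def phylomorpho_layout(phylo: Phylogeny, trait_x, trait_y):
    """Phylomorphospace coordinates: every node placed at (trait_x, trait_y).

    Tip coordinates are the observed trait values; internal coordinates come
    from :func:`asr_brownian`.  Returns ``(nodes, edges)`` where ``nodes`` has
    columns (node, x, y, is_tip) and ``edges`` is the list of (parent, child)
    label pairs mirroring the tree topology.
    """
    traits = pd.DataFrame({"x": pd.Series(dict(trait_x), dtype=float),
                           "y": pd.Series(dict(trait_y), dtype=float)})
    anc = asr_brownian(phylo, traits).estimates
    rows = [
        {"node": t, "x": traits.loc[t, "x"], "y": traits.loc[t, "y"], "is_tip": True}
        for t in phylo.tip_labels
    ] + [
        {"node": n, "x": anc.loc[n, "x"], "y": anc.loc[n, "y"], "is_tip": False}
        for n in phylo.internal_labels
    ]
    edges = [(p, c) for p, c, _ in phylo.edges()]
    return pd.DataFrame(rows), edges
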