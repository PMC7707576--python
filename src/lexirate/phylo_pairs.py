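"""Sister-pair (cherry) extraction from a time-calibrated phylogeny.

A sister pair is a pair of tip languages whose most recent common
ancestor is shared with no other sampled language.  Because every
retained pair descends from a distinct internal node, the pairs are
phylogenetically independent: each split is a separate natural
experiment in divergence.  Pairs are filtered on node support and on
divergence depth (pairs spanning essentially the whole tree are not
closely related languages and carry unreliable rate signal).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in years and optional node support."""

    tree: dendropy.Tree
    depth: float
    tip_labels: tuple[str, ...]
    ultrametric: bool


@dataclass(frozen=True)
class SisterPair:
    language_a: str
    language_b: str
    divergence_time: float  # height of the MRCA above the tips, years
    pair_path_length: float  # sum of the two tip branches, years
    support: float | None = None
    shared_nodes: int = 0

    @property
    def pair_id(self) -> str:
        return f"{self.language_a}|{self.language_b}"

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.language_a, self.language_b))


def parse_time_tree(newick: str | io.TextIOBase) -> Phylogeny:
    """Parse a Newick tree, normalise support labels, check ultrametricity.

    Internal-node labels in (1, 100] are taken to be percentage supports
    and rescaled to fractions with a warning.  Non-ultrametric trees are
    reported with a warning, never rejected: calibrated trees often carry
    rounding jitter.
    """
    text = newick.read() if hasattr(newick, "read") else newick
    if not text.strip():
        raise DataError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"malformed Newick: {exc}") from exc

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise DataError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise DataError("negative branch length in tree")

    _normalise_supports(tree)

    tree.calc_node_root_distances()
    tip_depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    depth = max(tip_depths) if tip_depths else 0.0
    ultrametric = depth == 0 or (max(tip_depths) - min(tip_depths)) <= max(
        ULTRAMETRIC_RTOL * depth, 1e-12
    )
    if not ultrametric:
        warnings.warn(
            f"tree is not ultrametric: tip heights span "
            f"[{min(tip_depths):g}, {max(tip_depths):g}]",
            stacklevel=2,
        )
    logger.info("parsed tree: %d tips, depth %g", len(tips), depth)
    return Phylogeny(tree=tree, depth=depth, tip_labels=tuple(tips), ultrametric=ultrametric)


def _normalise_supports(tree: dendropy.Tree) -> None:
    supports: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            supports[node] = float(node.label)
        except ValueError:
            continue
    if supports and max(supports.values()) > 1.0:
        if max(supports.values()) > 100.0:
            raise DataError("node support values exceed 100; scale not recognised")
        warnings.warn("node supports look like percentages; rescaling to [0, 1]", stacklevel=3)
        supports = {n: v / 100.0 for n, v in supports.items()}
    for node, value in supports.items():
        node.support = value  # type: ignore[attr-defined]
    for node in tree.preorder_node_iter():
        if not hasattr(node, "support"):
            node.support = None  # type: ignore[attr-defined]


def extract_cherries(
    phylogeny: Phylogeny, *, allow_polytomy_pairs: bool = False
) -> list[SisterPair]:
    """Return every two-tip internal node as a :class:`SisterPair`.

    Nodes with more than two children are never cherries under the
    default policy (the source trees are fully resolved); with
    ``allow_polytomy_pairs`` tip children of a polytomy are paired
    greedily in label order, keeping pairs disjoint.
    """
    pairs: list[SisterPair] = []
    for node in phylogeny.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        leaf_children = [c for c in children if c.is_leaf()]
        if len(children) == 2 and len(leaf_children) == 2:
            pairs.append(_make_pair(leaf_children[0], leaf_children[1], node))
        elif allow_polytomy_pairs and len(children) > 2 and len(leaf_children) >= 2:
            ordered = sorted(leaf_children, key=lambda c: c.taxon.label)
            for left, right in zip(ordered[::2], ordered[1::2]):
                pairs.append(_make_pair(left, right, node))
    logger.info("extracted %d cherries", len(pairs))
    return pairs


def _make_pair(left: dendropy.Node, right: dendropy.Node, mrca: dendropy.Node) -> SisterPair:
    la, lb = left.edge.length or 0.0, right.edge.length or 0.0
    shared = sum(1 for _ in mrca.ancestor_iter(inclusive=True))
    return SisterPair(
        language_a=left.taxon.label,
        language_b=right.taxon.label,
        divergence_time=(la + lb) / 2.0,  # == tip branch length when ultrametric
        pair_path_length=la + lb,
        support=getattr(mrca, "support", None),
        shared_nodes=shared,
    )


def filter_pairs(
    pairs: Sequence[SisterPair],
    *,
    min_support: float = 0.80,
    max_divergence: float | None = None,
    reject: Iterable[str | tuple[str, str] | frozenset[str]] = (),
) -> list[SisterPair]:
    """Apply support, divergence-depth and explicit-rejection filters.

    ``reject`` entries may be "A|B" strings or (a, b) tuples, matched
    regardless of orientation; it encodes external classification
    disagreements that cannot be detected from the tree itself.  Pairs
    with no recorded support pass the support filter (unknown, not bad).
    """
    reject_keys = {_reject_key(r) for r in reject}
    kept: list[SisterPair] = []
    for pair in pairs:
        if pair.key in reject_keys:
            logger.info("rejecting %s: in explicit reject list", pair.pair_id)
        elif pair.support is not None and pair.support < min_support:
            logger.info(
                "rejecting %s: support %.3f < %.3f", pair.pair_id, pair.support, min_support
            )
        elif max_divergence is not None and pair.divergence_time >= max_divergence:
            logger.info(
                "rejecting %s: divergence %.1f >= %.1f",
                pair.pair_id, pair.divergence_time, max_divergence,
            )
        else:
            kept.append(pair)
    return kept


def _reject_key(item: str | tuple[str, str] | frozenset[str]) -> frozenset[str]:
    if isinstance(item, str):
        return frozenset(item.split("|"))
    return frozenset(item)


def pairs_to_frame(pairs: Sequence[SisterPair]) -> pd.DataFrame:
    """Pair table in the supplementary-dataset shape."""
    return pd.DataFrame(
        [
            {
                "pair": p.pair_id,
                "language_a": p.language_a,
                "language_b": p.language_b,
                "shared_nodes": p.shared_nodes,
                "divergence_time": p.divergence_time,
                "pair_path_length": p.pair_path_length,
                "support": p.support,
            }
            for p in pairs
        ],
        columns=[
            "pair", "language_a", "language_b", "shared_nodes",
            "divergence_time", "pair_path_length", "support",
        ],
    )
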