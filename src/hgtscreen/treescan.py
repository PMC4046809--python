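"""Gene-tree topology screening on unrooted bipartitions.

A transfer call from a gene tree asks whether the focal (query) gene
forms a *supported clade with donor-group homologs to the exclusion of
the focal lineage's kin*.  Because the input trees are unrooted ML or
distance trees, "clade" here means one side of an internal-edge
bipartition: the test scans every internal edge, takes the side
containing the query, and passes if some edge with bootstrap support at
or above the threshold isolates the query together with at least one
donor-group leaf, any number of SELF leaves, zero KIN leaves, and — per
policy — zero (``strict``) or any (``lenient``, the default) leaves from
remaining groups.  Lenient is the default because real gene trees of
transferred genes routinely carry sporadic non-donor eukaryotes inside
the donor clade without invalidating the call.  Among passing edges the
one with the smallest query-side leaf set is reported.

Support conventions: edges without a support value count as support 0
(fail-closed — the screen demands explicit bootstrap support).  A branch
carrying two support values (e.g. ML and distance bootstraps written
``"95/87"``) is summarized by their minimum by default, which is the
conservative reading; ``dual_support="first"`` keeps the first value
only.  Trees whose supports are all fractional (posterior-style, in
[0, 1]) are rescaled to percent.

Batch screening over a tree collection uses a lower default threshold
(50) than curation (70): the batch screen is a recall-oriented first
pass, curation the precision-oriented final call.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import dendropy

from .detectors import DetectorVerdicts
from .taxonomy import Group, TaxonomyScheme

log = logging.getLogger(__name__)

__all__ = [
    "SCREEN_SUPPORT_DEFAULT",
    "CURATION_SUPPORT_DEFAULT",
    "DONOR_GROUPS_DEFAULT",
    "GeneTree",
    "CladeTestResult",
    "parse_tree",
    "clade_test",
    "batch_screen",
    "load_manifest",
]

SCREEN_SUPPORT_DEFAULT = 50.0
CURATION_SUPPORT_DEFAULT = 70.0
DONOR_GROUPS_DEFAULT = frozenset({Group.PROKARYOTE, Group.ALGA})


@dataclass
class GeneTree:
    """Unrooted, leaf-labeled gene tree with per-edge supports.

    ``splits`` stores one canonical side per internal edge (the side not
    containing the lexicographically smallest leaf) mapped to that edge's
    support, or None when the edge carries no support value.
    """

    query: str
    leaves: tuple[str, ...]
    groups: dict[str, Group]
    splits: dict[frozenset, float | None]
    newick: str = ""
    dtree: dendropy.Tree | None = field(default=None, repr=False, compare=False)

    def adjacency(self) -> dict:
        """Undirected node adjacency of the underlying tree."""
        adj: dict = {}
        for node in self.dtree.preorder_node_iter():
            for child in node.child_nodes():
                adj.setdefault(node, []).append(child)
                adj.setdefault(child, []).append(node)
        return adj


@dataclass
class CladeTestResult:
    passed: bool
    support: float | None
    clade_leaves: frozenset
    donor_composition: dict[Group, int]
    violation: str | None = None


def _parse_support(label: str | None, dual_support: str = "min") -> float | None:
    if label is None:
        return None
    text = str(label).strip()
    if not text or text == "*":
        # asterisks conventionally mark support below the display cutoff
        return None
    if "/" in text:
        parts = []
        for piece in text.split("/"):
            piece = piece.strip()
            if piece in ("", "*"):
                continue
            try:
                parts.append(float(piece))
            except ValueError:
                return None
        if not parts:
            return None
        return parts[0] if dual_support == "first" else min(parts)
    try:
        return float(text)
    except ValueError:
        log.warning("unparseable support label %r; treated as unknown", text)
        return None


def _resolve_taxon(
    label: str,
    scheme: TaxonomyScheme,
    query: str,
    taxon_of: Mapping[str, str] | Callable[[str], str] | None,
) -> str | None:
    if taxon_of is not None:
        taxon = (
            taxon_of.get(label) if isinstance(taxon_of, Mapping) else taxon_of(label)
        )
        if taxon is not None:
            return taxon
    if label in scheme:
        return label
    head = label.split("|")[0]
    if head in scheme:
        return head
    head = label.split("_")[0]
    if head in scheme:
        return head
    return None


def parse_tree(
    source: str | Path,
    scheme: TaxonomyScheme,
    query: str,
    taxon_of: Mapping[str, str] | Callable[[str], str] | None = None,
    dual_support: str = "min",
    scale_fractional: bool = True,
) -> GeneTree:
    """Read a bootstrap-annotated newick as an unrooted gene tree.

    ``source`` is a path or a newick string.  Leaf labels must be unique
    and include ``query``.  Every non-query leaf is mapped to a scheme
    taxon either through ``taxon_of`` (mapping or callable) or by trying
    the label itself and its ``|``/``_`` prefixes; an unmappable leaf is
    a hard error naming the leaf.  Supports are read from internal-node
    labels; missing or asterisk labels stay unknown.
    """
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc) or "same taxa" in str(exc):
            raise ValueError(f"duplicate leaf labels in newick: {exc}") from exc
        raise ValueError(f"malformed newick: {exc}") from exc
    leaves = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(set(leaves)) != len(leaves):
        dupes = sorted({l for l in leaves if leaves.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    if query not in leaves:
        raise ValueError(f"query leaf {query!r} missing from tree")

    groups: dict[str, Group] = {}
    for label in leaves:
        if label == query:
            groups[label] = Group.SELF
            continue
        taxon = _resolve_taxon(label, scheme, query, taxon_of)
        if taxon is None or taxon not in scheme:
            raise ValueError(f"leaf {label!r} cannot be mapped to a known taxon")
        groups[label] = scheme.group_of(taxon)

    anchor = min(leaves)
    all_leaves = frozenset(leaves)
    raw_splits: dict[frozenset, float | None] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) >= len(leaves) - 1:
            continue  # pendant-equivalent split under a bifurcating root
        canon = side if anchor not in side else all_leaves - side
        support = _parse_support(node.label, dual_support)
        prev = raw_splits.get(canon)
        if canon not in raw_splits or (support is not None and (prev is None or support > prev)):
            raw_splits[canon] = support
        else:
            raw_splits.setdefault(canon, support)

    numeric = [s for s in raw_splits.values() if s is not None]
    if scale_fractional and numeric and all(s <= 1.0 for s in numeric):
        raw_splits = {k: (None if s is None else s * 100.0) for k, s in raw_splits.items()}
        numeric = [s for s in raw_splits.values() if s is not None]
    bad = [s for s in numeric if not (0.0 <= s <= 100.0)]
    if bad:
        raise ValueError(f"support values outside [0, 100]: {sorted(bad)}")

    return GeneTree(
        query=query,
        leaves=leaves,
        groups=groups,
        splits=raw_splits,
        newick=text.strip(),
        dtree=tree,
    )


def clade_test(
    tree: GeneTree,
    donor_groups: frozenset[Group] = DONOR_GROUPS_DEFAULT,
    min_support: float = CURATION_SUPPORT_DEFAULT,
    allowed_other: str = "lenient",
) -> CladeTestResult:
    """Scan every internal edge for a supported query+donor clade.

    Failure is a result, not an error: the returned ``violation`` names
    the dominant reason (insufficient support, kin inside every candidate
    clade, no donor leaves at all, or no qualifying clade).
    """
    if not (0.0 <= min_support <= 100.0):
        raise ValueError("min_support must be in [0, 100]")
    if allowed_other not in ("lenient", "strict"):
        raise ValueError("allowed_other must be 'lenient' or 'strict'")
    all_leaves = frozenset(tree.leaves)
    neutral = {Group.SELF}
    best: tuple[int, float, tuple, frozenset, Counter] | None = None
    weak_composition = False
    kin_everywhere = True
    for side, support in tree.splits.items():
        qside = side if tree.query in side else all_leaves - side
        members = qside - {tree.query}
        counts = Counter(tree.groups[leaf] for leaf in members)
        has_donor = any(counts[g] for g in donor_groups)
        no_kin = counts[Group.KIN] == 0
        if no_kin:
            kin_everywhere = False
        others = sum(
            n for g, n in counts.items()
            if g not in donor_groups and g not in neutral and g is not Group.KIN
        )
        others_ok = allowed_other == "lenient" or others == 0
        if not (has_donor and no_kin and others_ok):
            continue
        value = support if support is not None else 0.0
        if value < min_support:
            weak_composition = True
            continue
        key = (len(qside), -value, tuple(sorted(qside)))
        if best is None or key < (best[0], best[1], best[2]):
            best = (len(qside), -value, tuple(sorted(qside)), frozenset(qside), counts)
    if best is not None:
        _, neg_support, _, clade, counts = best
        return CladeTestResult(
            passed=True,
            support=-neg_support,
            clade_leaves=clade,
            donor_composition=dict(counts),
        )
    donor_in_tree = any(
        tree.groups[leaf] in donor_groups for leaf in tree.leaves if leaf != tree.query
    )
    if weak_composition:
        violation = "insufficient_support"
    elif not donor_in_tree:
        violation = "no_donor_leaves"
    elif kin_everywhere:
        violation = "kin_in_clade"
    else:
        violation = "no_qualifying_clade"
    return CladeTestResult(
        passed=False,
        support=None,
        clade_leaves=frozenset(),
        donor_composition={},
        violation=violation,
    )


def batch_screen(
    trees: Mapping[str, GeneTree],
    donor_groups: frozenset[Group] = DONOR_GROUPS_DEFAULT,
    min_support: float = SCREEN_SUPPORT_DEFAULT,
    allowed_other: str = "lenient",
    detector_name: str = "treescan",
) -> DetectorVerdicts:
    """Screen a query -> GeneTree collection; one verdict per query."""
    queries = list(trees)
    predicted = [
        q
        for q, tree in trees.items()
        if clade_test(tree, donor_groups, min_support, allowed_other).passed
    ]
    verdicts = DetectorVerdicts(queries)
    verdicts.add_detector(
        detector_name,
        predicted,
        run_on=queries,
        provenance=f"clade_test min_support={min_support:g} "
        f"donors={sorted(g.value for g in donor_groups)} policy={allowed_other}",
    )
    return verdicts


def load_manifest(
    manifest_path: str | Path,
    scheme: TaxonomyScheme,
    taxon_of: Mapping[str, str] | Callable[[str], str] | None = None,
) -> tuple[dict[str, GeneTree], list[tuple[str, str]]]:
    """Load a (tree path, query leaf id) TSV manifest of gene trees.

    Tree paths are resolved relative to the manifest's directory.  Every
    query named in the manifest, and any ``sr_``-prefixed sister-species
    homolog leaf, resolves to the scheme's SELF lineage unless
    ``taxon_of`` says otherwise.  Unparseable trees become (query,
    reason) error records and are skipped; parsed trees are returned
    keyed by query.
    """
    base = Path(manifest_path).parent
    entries: list[tuple[str, str]] = []
    with open(manifest_path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() in ("tree_path", "path"):
                continue
            entries.append((parts[0], parts[1]))

    self_taxon = next(
        (t for t in scheme.taxa if scheme.group_of(t) is Group.SELF), None
    )
    queries = {q for _, q in entries}

    def resolve(label: str) -> str | None:
        if taxon_of is not None:
            taxon = (
                taxon_of.get(label) if isinstance(taxon_of, Mapping) else taxon_of(label)
            )
            if taxon is not None:
                return taxon
        if label in queries or label.startswith("sr_"):
            return self_taxon
        return None

    trees: dict[str, GeneTree] = {}
    errors: list[tuple[str, str]] = []
    for path, query in entries:
        try:
            trees[query] = parse_tree(base / path, scheme, query, taxon_of=resolve)
        except Exception as exc:  # malformed newick, missing file, bad leaf
            errors.append((query, str(exc)))
            log.warning("skipping tree for %r: %s", query, exc)
    return trees, errors
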