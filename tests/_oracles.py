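"""Independent oracles used by the test suite.

The clade oracle parses newick with Bio.Phylo and enumerates bipartitions
by its own traversal — a code path fully disjoint from the package's
dendropy-based implementation.  The alien-index oracle is a brute-force
scan over raw hit rows without any per-group indexing.
"""

from __future__ import annotations

import io
from collections import Counter

from Bio import Phylo

from hgtscreen.taxonomy import Group


def clade_oracle(
    newick: str,
    groups: dict[str, Group],
    query: str,
    donor_groups: frozenset,
    min_support: float,
    policy: str = "lenient",
):
    """Exhaustive bipartition enumeration via Bio.Phylo.

    Returns (passed, smallest_query_side_size_or_None, passing_sides)
    where passing_sides is a set of frozensets (query sides of passing
    edges).
    """
    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = frozenset(t.name for t in tree.get_terminals())
    passing: set[frozenset] = set()
    support_of: dict[frozenset, float] = {}
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue  # pendant-equivalent edge
        conf = float(clade.confidence) if clade.confidence is not None else 0.0
        qside = side if query in side else leaves - side
        members = qside - {query}
        counts = Counter(groups[l] for l in members)
        has_donor = any(counts[g] for g in donor_groups)
        no_kin = counts[Group.KIN] == 0
        others = sum(
            n
            for g, n in counts.items()
            if g not in donor_groups and g not in (Group.SELF, Group.KIN)
        )
        ok_other = policy == "lenient" or others == 0
        if has_donor and no_kin and ok_other and conf >= min_support:
            passing.add(qside)
            support_of[qside] = max(conf, support_of.get(qside, 0.0))
    if not passing:
        return False, None, passing, support_of
    smallest = min(len(s) for s in passing)
    return True, smallest, passing, support_of


def alien_index_oracle(
    rows,
    query: str,
    close_groups: frozenset,
    distant_groups: frozenset,
    threshold: float,
):
    """Brute-force alien index over (query_id, bitscore, group) rows."""
    close = [b for q, b, g in rows if q == query and g in close_groups]
    distant = [b for q, b, g in rows if q == query and g in distant_groups]
    close_best = max(close) if close else None
    distant_best = max(distant) if distant else None
    if close_best is None and distant_best is None:
        return None, False
    if distant_best is None:
        return 0.0, False
    if not close_best:
        return float("inf"), True
    ai = distant_best / close_best
    return ai, ai >= threshold
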