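# Methods

## Problem setting and model

`hgtscreen` addresses the curation half of a phylogenomic screen for
horizontally acquired genes in a phagotrophic protist genome.  The
inputs are artifacts a screen produces upstream: tabular homology hits
of every focal gene against a broad protein database, bootstrap-
annotated gene trees, a taxonomy assigning every subject taxon to a
lineage path, and optionally a second (sister-species) proteome and
functional annotations.  The package's job is everything after: taxon
grouping, hit filtering, candidate detection, tree testing, consensus
curation, event counting, and summary statistics.  Sequence search,
alignment and tree inference are deliberately out of scope.

The underlying evolutionary model is deliberately simple.  The focal
lineage (choanoflagellates in the shipped defaults) inherits most genes
vertically from its opisthokont ancestry, so a vertical gene's closest
homologs are metazoan/fungal (KIN).  A transferred gene's closest
homologs instead sit in its donor lineage — prokaryotes or "algae"
*sensu lato* — both in similarity space (higher bit scores) and in tree
space (the gene nests inside the donor clade).  "Algae" is broad by
design: every lineage with primary, secondary or tertiary plastids,
plus oomycetes and ciliates, which are conventionally treated as of
photosynthetic ancestry; a phagotroph's food pool does not respect
taxonomy textbooks.  Other eukaryotes are informative for neither side
and form their own group.

## Taxon grouping

Groups are resolved by longest-prefix match of semicolon-delimited
lineage paths against an ordered rule table (packaged default in
`data/group_prefixes.yaml`).  Prefix matching is robust to ranks missing
from individual records; the full lineage is retained so reports can
still separate archaeal from bacterial donors.  Taxa whose lineage root
is not a recognizable domain are dropped with per-row error records;
duplicate taxa with conflicting lineages are a hard error.  Sister
species of the focal lineage map to SELF: shared presence is read as
acquisition before the species split, never as evidence against
transfer.

## Hit filtering

Three exclusion rules, applied orderlessly (the suite asserts
commutativity): SELF-group hits, hits covering <10% of the query, and
pseudo-entries whose annotation contains "artificial sequence",
"synthetic construct" or "plasmid" (case-insensitive substrings).
Coverage is query-relative (alignment length / query length) — the
convention consistent with the upstream tree-building filter of ≥60%
query coverage.  When a query has several HSPs to one subject, the
maximum-bitscore HSP represents the pair, matching "top hit" semantics.
The two conventional E-value ceilings (1e-5 for the similarity screen,
1e-10 for tree screening) are configuration values, not constants.

## Detection

The alien index divides the best donor-group bit score by the best
kin bit score; candidates satisfy AI ≥ 1.2, threshold inclusive — the
convention that genes *below* 1.2 are the ones a default screen misses.
Other eukaryotes count toward neither side by default, but both group
sets are configurable.  Queries with no homology on either side are
reported separately and are never candidates: every transfer call here
rests on donor-group homology.  External detector output (e.g. from a
lineage-probability re-ranker or an automated tree pipeline) is imported
as candidate lists and tracked as tri-state flags (predicted /
not-predicted / not-run), so multi-program consensus accounting works
without reimplementing those programs.

## Tree testing

Monophyly is evaluated on unrooted bipartitions, since input trees are
unrooted ML/distance trees: "a clade of the query with donors" means an
internal edge whose query side holds the query, ≥1 donor leaf, any SELF
leaves, zero KIN leaves, and — policy-dependent — other-eukaryote
leaves (allowed under the default `lenient` policy, since real
transferred-gene trees routinely carry sporadic non-donor eukaryotes
inside the donor clade; `strict` is available).  Among passing edges the
smallest query side is reported, which also drives donor classification.
Numerical conventions: edges without a support value count as support 0
(fail-closed — the screen demands explicit bootstrap support); a branch
carrying two supports ("95/87", ML and distance bootstraps) is
summarized by their minimum by default — whether both analyses must
individually clear the bar is genuinely open, and the minimum is the
conservative reading (`dual_support="first"` keeps the ML value);
asterisk labels (conventionally "below display cutoff") are unknown,
hence 0; trees whose numeric supports are all ≤1 are read as fractional
and rescaled to percent (a tree whose supports are genuinely all ≤1% is
misread by this heuristic; disable with `scale_fractional=False`).
Screening uses support ≥50 (recall-oriented batch pass), curation ≥70
(precision-oriented final call).

## Curation

A gene is ACCEPTED by either evidence route: a passing 70% clade test,
or a restricted phyletic pattern (homologs only in the focal lineage
plus prokaryotes and/or algae — such genes often lack enough taxa for a
meaningful tree).  Both routes are recorded.  A curated candidate whose
tree fails and whose pattern is broad is REJECTED; a gene without usable
evidence (no tree, no homology) is NO_CALL.  Donor class: all-alga
clade → ALGA, all-prokaryote → BACTERIA, mixed → EITHER; pattern-route
calls fall back on the pattern, with PROK_ALGA_ONLY resolved by the
margin between best alga and best prokaryote bit scores (relative
difference < 0.1 → EITHER; no published numeric rule exists for the
ambiguous class, so the margin is explicit and configurable).
Direction: restricted patterns and donor-affiliated broad-pattern clades
are transfer *into* the focal genome — the phagotroph eats the donors,
donors are older lineages, and the reverse direction would require
ancestors of major bacterial/algal groups as recipients; anything else
is UNDETERMINED.  Manual-inspection evidence (shared indels, conserved
residues, gene structure, alignment quality) is a free-form checklist
on each record, set by an operator, never decided algorithmically.  The
scaffold-neighbor contamination heuristic — flag accepted genes whose
genomic neighbors all lack kin affiliation — is provided as an optional
helper over a gene-order table.

Event collapsing: within one family tree, accepted focal leaves in a
maximal clade containing no non-focal, non-SELF leaf form one
acquisition event; focal leaves separated by donor leaves are separate
events; families are never merged across trees (cross-family merging by
shared donor would be speculation, and published event totals are
explicitly estimates).  The computation runs on the unrooted topology,
so it is invariant to rooting and child order — asserted by the suite
over random re-rootings.

## Synthetic data

The simulator emulates the *structure* of screen inputs, not sequences.
Bit scores follow `base − decay·distance + noise`, floored at 0, with
per-taxon jitter; E-values are a fixed strictly decreasing function of
the bit score (only the ordering is contractual).  Group distances make
kin closest for vertical genes (1 < 2 < 3 < 4 decay units for
KIN/OTHER/ALGA/PROKARYOTE) and the donor closest (0.5 units) for
transfers, so at the default decay of 40 bits/unit the alien index
separates the classes by a wide deterministic margin at zero noise.
Trees are built on a fixed 20-taxon scaffold spanning all five groups;
transferred queries are regrafted inside the donor clade with the
attachment support drawn from the strong range (85–100), and ambiguous
("EITHER") donors get a mixed alga+cyanobacterium sister clade.  Weak
mode (`weak_support_fraction`) models a poorly resolved gene tree by
drawing *every* support from the weak range — weakening only the
attachment edge would be ineffective, because a larger donor clade
enclosing the query would still clear the curation bar.  Duplication
after transfer yields two-gene families with sister paralogs, giving
planted event counts below planted gene counts.  A configurable
fraction of transfers is "restricted" (no kin/other-eukaryote homologs)
to exercise the pattern route.  Default study conditions: 500 genes,
20% transferred, donor mix 59.3/34.3/6.4% (alga/bacteria/either),
52.6% of transfers predating the sister-species split, duplication
probability 0.2 — the proportions of the curated screen the fixture
mirrors.

Every draw flows from one seeded generator, and bit-score noise is
applied as `noise_sd × z` with pre-drawn standard normals, so runs with
the same seed share deviates across noise levels (common random
numbers); per-gene detection is then provably monotone in `noise_sd`,
which is what makes the noise-grid sensitivity check deterministic per
seed rather than a tolerance game.  Emitted files carry a config hash.

What passing on synthetic data does *not* show: real screens face
database composition bias, alignment and long-branch artifacts,
differential loss mimicking transfer, contamination, and support values
correlated with alignment quality — none of which the generator models.
The simulation validates the *bookkeeping and decision logic* of the
pipeline, not the biological error rate of a real screen.

## Fixture and reporting

The packaged 405-row ledger mirrors a published curated gene table for
a choanoflagellate proteome at the level of its printed marginals:
donor classes 240/139/26 with ~210/100/20 events, detector totals
358/345/204 over a union of 388 with 17 genes missed by all three,
sharing split 213/192, and 193 categorized genes (62 carbohydrate, 22
amino-acid, 45 transporter/stress, 64 other; 89 unknown-with-domains
and 123 unknown excluded from the denominator).  The joint detector
assignment is one deterministic arrangement consistent with all
marginals, which is the most the published figures determine; detector
total-candidate counts (833/1438/600) are back-derived from the
published positive rates (43/24/34%).  All reported percentages round
half-up to one decimal — the rule under which every reproducible
published percentage verifies.  Percentage denominators are explicit in
the report object (union for detector shares, categorized subset for
category percentages); the sum-to-100 check applies only to exclusive
category partitions.

## Verification strategy

Two dual-route checks anchor correctness: the clade test is compared
against an exhaustive bipartition enumeration built on Bio.Phylo (a
parser and traversal entirely disjoint from the dendropy-based
implementation), and the alien index against a brute-force scan over
raw rows with no group indexing.  Invariants — filter commutativity and
monotonicity, threshold monotonicity, rooting/child-order invariance,
event count ≤ accepted count — are property-tested (hypothesis,
derandomized, plus seeded random-structure loops).  Problem sizes in the
default suite and acceptance script (500-gene simulations, 200 random
trees, 1000 random hit tables) are chosen to exercise every code path
with comfortable margins while keeping a full run in tens of seconds.

## Known limitations

No taxid resolution or synonym handling (exact taxon names only); no
HSP chaining; no reconciliation-based or probabilistic transfer
inference; no automated detection of shared indels or conserved
residues; event estimates never merge families; the lineage-probability
and automated-tree-pipeline detectors are consumed as candidate lists,
not reimplemented.
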