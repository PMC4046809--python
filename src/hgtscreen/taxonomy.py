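"""Taxon grouping for horizontal-gene-transfer screening.

Every subject taxon in a homology search, and every leaf of a gene tree,
is assigned to one of five analysis groups relative to the focal genome:

* ``SELF`` — the focal lineage (choanoflagellates by default).  Hits from
  this group are excluded from screening; tree leaves from it are allowed
  inside candidate clades, since shared presence in a sister species is
  read as acquisition before the species split, not as evidence against
  transfer.
* ``KIN`` — the vertical relatives of the focal lineage (metazoans and
  fungi for a choanoflagellate).  A gene whose best homologs are here is
  presumed vertically inherited.
* ``PROKARYOTE`` — bacteria and archaea, the classic donor pool.
* ``ALGA`` — "algae" sensu lato: every lineage carrying primary,
  secondary or tertiary plastids (green plants, glaucophytes, red algae,
  alveolates, cryptophytes, euglenids, haptophytes, chlorarachniophytes,
  stramenopiles) plus oomycetes and ciliates, which are conventionally
  treated as of photosynthetic ancestry.
* ``OTHER_EUK`` — any other eukaryote.

Assignment works on semicolon-delimited lineage paths (root first) by
longest-prefix match against a group-definition table, which makes it
robust to ranks missing from individual records.  The full taxon record
keeps the lineage, so reports can still distinguish e.g. archaeal from
bacterial donors inside ``PROKARYOTE``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

log = logging.getLogger(__name__)

__all__ = [
    "Group",
    "GroupConfig",
    "TaxonomyScheme",
    "RowError",
    "load_scheme",
    "save_scheme",
    "default_scheme",
]


class Group(str, enum.Enum):
    """Analysis group of a taxon relative to the focal genome."""

    SELF = "SELF"
    KIN = "KIN"
    PROKARYOTE = "PROKARYOTE"
    ALGA = "ALGA"
    OTHER_EUK = "OTHER_EUK"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Lineage roots from which a group can be resolved at all.
DOMAIN_ROOTS = ("Eukaryota", "Bacteria", "Archaea")


def _split_lineage(text: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in text.split(";") if part.strip())


@dataclass(frozen=True)
class GroupConfig:
    """Ordered lineage-prefix -> group rules; the longest prefix wins."""

    rules: tuple[tuple[tuple[str, ...], Group], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GroupConfig":
        rules = []
        for group_name, prefixes in mapping.items():
            group = Group(group_name.upper())
            for prefix in prefixes:
                rules.append((_split_lineage(prefix), group))
        return cls(rules=tuple(rules))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "GroupConfig":
        ref = resources.files("hgtscreen.data").joinpath("group_prefixes.yaml")
        return cls.from_mapping(yaml.safe_load(ref.read_text()))

    def assign(self, lineage: tuple[str, ...]) -> Group | None:
        """Group for a lineage path, or None when no rule matches."""
        best: Group | None = None
        best_len = -1
        for prefix, group in self.rules:
            n = len(prefix)
            if n <= len(lineage) and tuple(lineage[:n]) == prefix and n > best_len:
                best, best_len = group, n
        return best

    def _last_elements(self, group: Group) -> set[str]:
        return {prefix[-1] for prefix, g in self.rules if g is group}

    @property
    def algal_groups(self) -> set[str]:
        return self._last_elements(Group.ALGA)

    @property
    def self_lineage(self) -> str:
        names = sorted(self._last_elements(Group.SELF))
        return names[0] if names else ""

    @property
    def kin_lineages(self) -> set[str]:
        return self._last_elements(Group.KIN)


@dataclass
class RowError:
    """A dropped input row, with the reason it could not be used."""

    row: int
    taxon: str
    reason: str


@dataclass
class TaxonomyScheme:
    """Concrete taxon -> group assignment under a :class:`GroupConfig`.

    ``group_of_taxon`` holds the resolved label for every loaded taxon;
    ``lineage_of`` retains the full lineage path so the domain (bacteria
    vs archaea vs eukaryotes) stays recoverable.
    """

    group_of_taxon: dict[str, Group]
    lineage_of: dict[str, tuple[str, ...]]
    config: GroupConfig = field(default_factory=GroupConfig.default)
    errors: list[RowError] = field(default_factory=list)

    def group_of(self, taxon: str) -> Group:
        try:
            return self.group_of_taxon[taxon]
        except KeyError:
            raise KeyError(f"unknown taxon: {taxon!r}") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.group_of_taxon

    def domain_of(self, taxon: str) -> str:
        return self.lineage_of[taxon][0]

    @property
    def taxa(self) -> list[str]:
        return list(self.group_of_taxon)

    @property
    def algal_groups(self) -> set[str]:
        return self.config.algal_groups

    @property
    def self_lineage(self) -> str:
        return self.config.self_lineage

    @property
    def kin_lineages(self) -> set[str]:
        return self.config.kin_lineages

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        config: GroupConfig | None = None,
    ) -> "TaxonomyScheme":
        """Build a scheme from (taxon, lineage-path) pairs.

        A duplicate taxon with a conflicting lineage is a hard error; a
        lineage whose root is not a recognizable domain produces a
        per-row error record and the row is dropped with a warning.
        """
        config = config or GroupConfig.default()
        group_of: dict[str, Group] = {}
        lineage_of: dict[str, tuple[str, ...]] = {}
        errors: list[RowError] = []
        for row, (taxon, lineage_text) in enumerate(records, start=1):
            taxon = taxon.strip()
            lineage = _split_lineage(lineage_text)
            if not taxon or not lineage:
                errors.append(RowError(row, taxon, "empty taxon or lineage"))
                continue
            if taxon in lineage_of:
                if lineage_of[taxon] != lineage:
                    raise ValueError(
                        f"duplicate taxon {taxon!r} with conflicting lineages: "
                        f"{lineage_of[taxon]} vs {lineage}"
                    )
                continue
            group = config.assign(lineage)
            if group is None:
                errors.append(
                    RowError(row, taxon, f"unresolvable domain for lineage {lineage}")
                )
                log.warning("dropping taxon %r: unresolvable domain %s", taxon, lineage)
                continue
            group_of[taxon] = group
            lineage_of[taxon] = lineage
        return cls(group_of_taxon=group_of, lineage_of=lineage_of, config=config,
                   errors=errors)

    def to_records(self) -> list[tuple[str, str]]:
        return [(t, ";".join(self.lineage_of[t])) for t in self.group_of_taxon]


def load_scheme(path: str | Path, config: GroupConfig | None = None) -> TaxonomyScheme:
    """Load a two-column (taxon, lineage-path) TSV into a scheme.

    Lines starting with '#' are comments; a header line naming the two
    columns is accepted and skipped.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"taxonomy row needs two tab-separated columns: {line!r}")
            if parts[0].strip().lower() == "taxon":
                continue
            records.append((parts[0], parts[1]))
    return TaxonomyScheme.from_records(records, config=config)


def save_scheme(scheme: TaxonomyScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tlineage\n")
        for taxon, lineage in scheme.to_records():
            fh.write(f"{taxon}\t{lineage}\n")


def default_scheme(config: GroupConfig | None = None) -> TaxonomyScheme:
    """The packaged scheme: a ~20-taxon scaffold spanning all five groups."""
    ref = resources.files("hgtscreen.data").joinpath("default_taxa.tsv")
    records = []
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("taxon\t"):
            continue
        taxon, lineage = line.split("\t")[:2]
        records.append((taxon, lineage))
    return TaxonomyScheme.from_records(records, config=config)
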