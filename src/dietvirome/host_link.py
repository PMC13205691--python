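"""Phage-host linking by taxonomic nomenclature.

A phage species name such as ``s__Bacteroides_phage`` encodes its candidate
bacterial host genus as the first genus-like token. Linking emits a
(phage, bacterium) pair whenever that parsed genus exactly matches the
bacterium's genus. crAssphages are a special case: their names carry no host
genus, but the clade is a well-characterized Bacteroides phage group, so any
name containing "crass" is assigned host genus Bacteroides (phylum
Bacteroidetes) by override.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "HostLink",
    "PHAGE_DESIGNATORS",
    "parse_host_genus",
    "parse_bacterial_genus",
    "link_pairs",
    "rollup_phylum",
]

#: Tokens marking the phage/virus designator in a species-name string. A
#: capitalized genus token only counts as the host genus when one of these
#: follows it somewhere in the name.
PHAGE_DESIGNATORS = frozenset(
    {
        "phage",
        "phages",
        "virus",
        "viruses",
        "siphovirus",
        "myovirus",
        "podovirus",
        "microvirus",
        "prophage",
    }
)

CRASS_HOST_GENUS = "Bacteroides"
CRASS_HOST_PHYLUM = "Bacteroidetes"


@dataclass(frozen=True)
class HostLink:
    phage_taxon_id: str
    host_genus: str
    host_phylum: str | None
    method: str  # nomenclature | crassphage_override | provided
    ambiguous: bool = False  # more than one capitalized token preceded the designator

    def __post_init__(self) -> None:
        if self.method == "crassphage_override":
            if self.host_genus != CRASS_HOST_GENUS or self.host_phylum != CRASS_HOST_PHYLUM:
                raise ValueError("crassphage_override links must point to Bacteroides/Bacteroidetes")


def _strip_rank_prefix(name: str) -> str:
    for prefix in ("s__", "s_"):
        if name.startswith(prefix):
            return name[len(prefix) :]
    return name


def _is_genus_like(token: str) -> bool:
    return len(token) > 0 and token[0].isupper() and token.lower() not in PHAGE_DESIGNATORS


def parse_host_genus(species_name: str) -> tuple[str | None, str, bool]:
    """Extract the candidate host genus from a phage species-name string.

    Returns ``(genus, method, ambiguous)``. Names containing "crass"
    (case-insensitive) return Bacteroides with method ``crassphage_override``.
    Otherwise the first capitalized genus-like token that precedes a phage
    designator token is returned with method ``nomenclature``; ``ambiguous``
    is set when more than one capitalized token precedes the designator.
    Unparseable names yield ``(None, "none", False)``.
    """
    if not species_name:
        raise ValueError("species_name must be nonempty")
    if "crass" in species_name.lower():
        return CRASS_HOST_GENUS, "crassphage_override", False
    tokens = _strip_rank_prefix(species_name).split("_")
    designator_idx = next((i for i, t in enumerate(tokens) if t.lower() in PHAGE_DESIGNATORS), None)
    if designator_idx is None:
        return None, "none", False
    capitalized = [t for t in tokens[:designator_idx] if _is_genus_like(t)]
    if not capitalized:
        return None, "none", False
    return capitalized[0], "nomenclature", len(capitalized) > 1


def parse_bacterial_genus(species_name: str) -> str | None:
    """Genus of a bacterial species name: the first token after the rank prefix."""
    if not species_name:
        return None
    first = _strip_rank_prefix(species_name).split("_")[0]
    return first if first and first[0].isupper() else None


def link_pairs(
    phages: pd.DataFrame,
    bacteria: pd.DataFrame,
    case_sensitive: bool = True,
    taxonomy: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Emit every (phage_id, bacterium_id) pair with matching host genus.

    ``phages`` and ``bacteria`` are annotation tables (``taxon_id``,
    ``species_name``, optionally ``host_genus``/``host_link_method``). A
    phage's host genus is taken from its annotation when
    ``host_link_method == "provided"``, otherwise parsed from the species
    name. Matching is exact and case-sensitive by default. crAssphage links
    pair with every Bacteroides bacterium. Output is canonically sorted and
    free of duplicates.
    """
    links = build_links(phages, taxonomy)
    bact_genus: dict[str, str] = {}
    for _, row in bacteria.iterrows():
        genus = row.get("host_genus") or parse_bacterial_genus(str(row["species_name"]))
        if genus:
            bact_genus[str(row["taxon_id"])] = genus

    def norm(g: str) -> str:
        return g if case_sensitive else g.lower()

    pairs = {
        (link.phage_taxon_id, b_id)
        for link in links
        for b_id, b_genus in bact_genus.items()
        if norm(link.host_genus) == norm(b_genus)
    }
    return sorted(pairs)


def build_links(phages: pd.DataFrame, taxonomy: Mapping[str, str] | None = None) -> list[HostLink]:
    """One HostLink per linkable phage annotation row."""
    links: list[HostLink] = []
    for _, row in phages.iterrows():
        method = row.get("host_link_method")
        if method == "provided" and row.get("host_genus"):
            genus = str(row["host_genus"])
            phylum = row.get("host_phylum") or (rollup_phylum(genus, taxonomy) if taxonomy else None)
            links.append(HostLink(str(row["taxon_id"]), genus, phylum, "provided"))
            continue
        genus, parse_method, ambiguous = parse_host_genus(str(row["species_name"]))
        if genus is None:
            continue
        if parse_method == "crassphage_override":
            phylum = CRASS_HOST_PHYLUM
        else:
            phylum = rollup_phylum(genus, taxonomy) if taxonomy else None
        links.append(HostLink(str(row["taxon_id"]), genus, phylum, parse_method, ambiguous))
    return sorted(links, key=lambda l: (l.phage_taxon_id, l.host_genus))


def rollup_phylum(genus: str, taxonomy_table: Mapping[str, str] | None) -> str | None:
    """Genus -> phylum lookup; None when the genus is absent from the table."""
    if taxonomy_table is None:
        return None
    return taxonomy_table.get(genus)
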