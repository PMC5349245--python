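"""Eight-rank lineages: resolution, quality control, and the rank tree.

Naive-Bayes classifiers of the RDP family train on a fixed-depth
taxonomy, so every reference sequence carries exactly eight ranks:
Root, Kingdom, Phylum, Class, Order, Family, Genus, Species.  Source
taxonomies are read in the NCBI taxdump dialect (nodes + names tables);
any other rank in the source path is ignored.

Three quality filters are applied to each lineage, in order:

I.   the species rank must hold a binomial (genus + epithet) — a proxy
     for identification by a trained taxonomist;
II.  no rank name may contain a token indicating uncertain identity
     ('cf.', 'aff.', 'sp.', ...);
III. the species name must not contain a known non-Latin identifier.

Duplicate taxon names above the species level (the same genus name in
two unrelated higher groups, an error that nonetheless occurs) abort
classifier training, so conflicting occurrences are renamed by
appending a distinguishing two-digit number (Automolus → Automolus01).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .events import CurationEvent, Reason

#: The seven named ranks below Root, in depth order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Rank abbreviations used in placeholder names for missing ranks.
RANK_ABBREV = {
    "kingdom": "kin", "phylum": "phy", "class": "cla", "order": "ord",
    "family": "fam", "genus": "gen", "species": "spe",
}

_PLACEHOLDER_RE = re.compile(r"_(kin|phy|cla|ord|fam|gen|spe)$")

ROOT_NAME = "Root"


def is_placeholder(name: str) -> bool:
    """True for names synthesised to fill a missing rank (``Automolus_fam``)."""
    return name == ROOT_NAME or _PLACEHOLDER_RE.search(name) is not None


@dataclass(frozen=True)
class Lineage:
    """One eight-rank lineage, Root through Species."""

    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str
    root: str = ROOT_NAME

    def levels(self) -> tuple[str, ...]:
        """All eight names in depth order, Root first."""
        return (self.root, self.kingdom, self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)

    def named_levels(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(("root",) + RANKS, self.levels()))

    @classmethod
    def from_levels(cls, levels: Sequence[str]) -> "Lineage":
        if len(levels) != 8:
            raise ValueError(f"expected 8 levels, got {len(levels)}")
        if any(not name for name in levels):
            raise ValueError("empty rank name")
        return cls(root=levels[0], kingdom=levels[1], phylum=levels[2],
                   class_=levels[3], order=levels[4], family=levels[5],
                   genus=levels[6], species=levels[7])


@dataclass(frozen=True)
class TaxonNode:
    """One node of a taxonomy: id, name, parent id, rank."""

    taxid: int
    name: str
    parent_taxid: int
    rank: str


class TaxdumpIndex(Mapping[int, list[str]]):
    """Index over an NCBI-taxdump-dialect nodes + names table pair.

    Acts as a mapping taxid → ancestor names (root first, the node's
    own name last), which is the protocol the metazoan pre-filter
    consumes.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node

    @classmethod
    def from_taxdump(cls, nodes_text: str, names_text: str) -> "TaxdumpIndex":
        """Parse ``nodes.dmp`` / ``names.dmp`` content ("\\t|\\t"-delimited)."""
        names: dict[int, str] = {}
        for line in names_text.splitlines():
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\t|").split("\t|\t")]
            if len(fields) < 4 or fields[3] != "scientific name":
                continue
            names[int(fields[0])] = fields[1]
        nodes = []
        for line in nodes_text.splitlines():
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\t|").split("\t|\t")]
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes.append(TaxonNode(taxid, names.get(taxid, f"taxid{taxid}"),
                                   parent, rank))
        return cls(nodes)

    def node(self, taxid: int) -> TaxonNode:
        return self._nodes[taxid]

    def path(self, taxid: int) -> list[TaxonNode]:
        """Root-to-node chain; raises LookupError on unknown ids or cycles."""
        if taxid not in self._nodes:
            raise LookupError(f"unknown taxid {taxid}")
        chain: list[TaxonNode] = []
        seen: set[int] = set()
        cur = taxid
        while True:
            if cur in seen:
                raise LookupError(f"taxid {taxid}: cycle at {cur}")
            seen.add(cur)
            node = self._nodes.get(cur)
            if node is None:
                raise LookupError(f"taxid {taxid}: dangling parent {cur}")
            chain.append(node)
            if node.parent_taxid == node.taxid:
                break
            cur = node.parent_taxid
        chain.reverse()
        return chain

    def ancestor_names(self, taxid: int) -> list[str]:
        return [n.name for n in self.path(taxid)]

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, taxid: int) -> list[str]:
        try:
            return self.ancestor_names(taxid)
        except LookupError:
            raise KeyError(taxid) from None

    def __iter__(self):
        return iter(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)


def resolve_lineage(taxid: int, index: TaxdumpIndex) -> Lineage:
    """Read the eight ranks off a taxon's root-to-node path.

    A missing rank is filled with ``{nearest named neighbour}_{abbrev}``
    — the nearest real name below the gap if one exists, else the
    nearest above — so the lineage keeps its fixed depth while staying
    recognisably synthetic at that level.

    Raises LookupError when the taxid cannot be resolved.
    """
    path = index.path(taxid)
    by_rank: dict[str, str] = {}
    for node in path:
        if node.rank in RANK_ABBREV and node.rank not in by_rank:
            by_rank[node.rank] = node.name
    values: list[str | None] = [by_rank.get(rank) for rank in RANKS]
    filled: list[str] = []
    for i, value in enumerate(values):
        if value is not None:
            filled.append(value)
            continue
        donor = next((v for v in values[i + 1:] if v is not None), None)
        if donor is None:
            donor = next((v for v in reversed(values[:i]) if v is not None), None)
        if donor is not None:
            base = donor.split()[0]  # genus token of a binomial donor
        else:
            base = ROOT_NAME
        filled.append(f"{base}_{RANK_ABBREV[RANKS[i]]}")
    return Lineage.from_levels([ROOT_NAME] + filled)


@dataclass(frozen=True)
class QCPolicy:
    """The three lineage quality filters and their parameter lists."""

    forbidden_tokens: tuple[str, ...] = (
        "cf.", "aff.", "sp.", "environment", "undescribed", "uncultured",
        "complex", "unclassified", "nom.", "nud.", "unidentif",
    )
    blacklist_ids: tuple[str, ...] = ("sp0936BC", "MG98.09", "sp0942A", "EEG-2007")
    require_binomial: bool = True


def qc_lineage(
    lineage: Lineage, policy: QCPolicy | None = None, subject: str = ""
) -> CurationEvent | None:
    """Apply filters I–III in order; None means the lineage passes.

    I: species must be a real binomial (≥2 whitespace tokens, not a
    placeholder).  II: no rank name may contain a forbidden token as a
    case-insensitive substring.  III: the species name must not contain
    a blacklisted identifier.  The first failing filter is reported.
    """
    if policy is None:
        policy = QCPolicy()
    species = lineage.species
    if policy.require_binomial and (
        is_placeholder(species) or len(species.split()) < 2
    ):
        return CurationEvent(subject, "taxonomy_qc", Reason.NO_SPECIES_RANK,
                             f"species={species!r}")
    lowered_tokens = [t.casefold() for t in policy.forbidden_tokens]
    for rank_name, name in lineage.named_levels():
        low = name.casefold()
        for token in lowered_tokens:
            if token in low:
                return CurationEvent(
                    subject, "taxonomy_qc", Reason.FORBIDDEN_TOKEN,
                    f"{rank_name}={name!r} contains {token!r}")
    for ident in policy.blacklist_ids:
        if ident in species:
            return CurationEvent(subject, "taxonomy_qc", Reason.BLACKLISTED_ID,
                                 f"species={species!r} contains {ident!r}")
    return None


RenameMap = dict[tuple[str, tuple[str, ...], str], str]


def resolve_name_conflicts(
    lineages: Sequence[Lineage],
) -> tuple[list[Lineage], RenameMap]:
    """Rename duplicate taxon names above the species level.

    An *occurrence* of a name is its (rank, parent path) context.  When
    a non-placeholder name has more than one occurrence — same rank
    under different parents, or two different ranks — every occurrence
    except the first in (rank, parent path) sort order gets a two-digit
    suffix ("01", "02", ... assigned in that order).  A renamed genus
    is propagated into the first token of its species binomials, so the
    binomial invariant survives.  The operation is idempotent.

    Returns the rewritten lineages (input order preserved) and the map
    ``(rank, parent path, old name) → new name``.
    """
    # collect occurrences of each bare name over ranks kingdom..genus
    occurrences: dict[str, set[tuple[int, tuple[str, ...]]]] = {}
    for lin in lineages:
        levels = lin.levels()
        for rank_idx in range(1, 7):  # kingdom .. genus
            name = levels[rank_idx]
            if is_placeholder(name):
                continue
            occurrences.setdefault(name, set()).add(
                (rank_idx, levels[:rank_idx]))
    taken = set(occurrences)
    renames: dict[tuple[int, tuple[str, ...], str], str] = {}
    for name in sorted(occurrences):
        occs = sorted(occurrences[name])
        if len(occs) < 2:
            continue
        counter = 0
        for rank_idx, parent in occs[1:]:
            counter += 1
            width = 2
            while True:
                candidate = f"{name}{counter:0{width}d}"
                if candidate not in taken:
                    break
                counter += 1
                if counter >= 10 ** width:
                    width += 1
            taken.add(candidate)
            renames[(rank_idx, parent, name)] = candidate
    out: list[Lineage] = []
    public_map: RenameMap = {}
    for lin in lineages:
        levels = list(lin.levels())
        original = lin.levels()
        for rank_idx in range(1, 7):
            key = (rank_idx, original[:rank_idx], original[rank_idx])
            new = renames.get(key)
            if new is not None:
                levels[rank_idx] = new
                public_map[(RANKS[rank_idx - 1], original[:rank_idx],
                            original[rank_idx])] = new
        # keep the species binomial's genus token aligned with the genus rank
        genus = levels[6]
        species_tokens = levels[7].split()
        if (not is_placeholder(levels[7]) and len(species_tokens) >= 2
                and species_tokens[0] != genus and not is_placeholder(genus)):
            levels[7] = " ".join([genus] + species_tokens[1:])
        out.append(Lineage.from_levels(levels))
    return out, public_map


def rename_map_to_tsv(rename_map: RenameMap) -> str:
    lines = ["rank\told_name\tnew_name"]
    for (rank, _parent, old), new in sorted(
        rename_map.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[1])
    ):
        lines.append(f"{rank}\t{old}\t{new}")
    return "\n".join(lines) + "\n"


#: RDP-style rank labels by depth 0..7.
TREE_RANKS = ("rootrank",) + RANKS


def build_rank_tree(lineages: Sequence[Lineage]) -> list[TaxonNode]:
    """Materialise the eight-level tree spanned by *lineages*.

    Node ids are dense from 0 (the root), assigned in deterministic
    depth-first order with children visited in lexical name order.
    Raises ValueError if a residual duplicate (same non-placeholder
    name, same rank, different parents) survives — the conflict
    resolver must run first.
    """
    children: dict[tuple[str, ...], set[str]] = {(ROOT_NAME,): set()}
    for lin in lineages:
        levels = lin.levels()
        if levels[0] != ROOT_NAME:
            raise ValueError(f"lineage root must be {ROOT_NAME!r}")
        for depth in range(1, 8):
            parent = levels[:depth]
            children.setdefault(parent, set()).add(levels[depth])
            children.setdefault(levels[:depth + 1], set())
    # residual duplicate check over ranks kingdom..genus
    seen: dict[tuple[int, str], tuple[str, ...]] = {}
    for path in children:
        depth = len(path) - 1
        if not (1 <= depth <= 6) or is_placeholder(path[-1]):
            continue
        key = (depth, path[-1])
        if key in seen and seen[key] != path[:-1]:
            raise ValueError(
                f"duplicate name {path[-1]!r} at rank {TREE_RANKS[depth]} "
                "under different parents; run resolve_name_conflicts first")
        seen.setdefault(key, path[:-1])
    nodes: list[TaxonNode] = []
    ids: dict[tuple[str, ...], int] = {}

    def visit(path: tuple[str, ...], parent_id: int) -> None:
        node_id = len(nodes)
        ids[path] = node_id
        depth = len(path) - 1
        nodes.append(TaxonNode(node_id, path[-1], parent_id, TREE_RANKS[depth]))
        for child in sorted(children.get(path, ())):
            visit(path + (child,), node_id)

    visit((ROOT_NAME,), -1)
    return nodes
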