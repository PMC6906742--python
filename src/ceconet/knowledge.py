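"""Genome-annotation knowledge base and the genus-reaction capability model.

The central object is a binary genus x reaction presence matrix assembled by
joining organism-level ortholog (KO) and enzyme-class (EC) assignments to
reaction identifiers, in the style of the KEGG-derived organism-reaction
matrices used for gut-community metabolic modelling.  Reactions carry primary
substrate-product compound pairs, from which each genus's metabolite
capability set (the compounds any of its member organisms can act on) is
derived.  Mechanistic-versus-empirical classification of correlation edges and
network-neighborhood annotation scoring both sit on top of these structures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KnowledgeBase",
    "ORMatrix",
    "GenusMetaboliteMap",
    "CoverageReport",
    "KnowledgeBaseFormatError",
    "load_knowledge_base",
    "build_or_matrix",
    "derive_genus_metabolite_map",
    "model_coverage",
    "normalize_genus",
]

SOURCE_TAGS = frozenset({"kegg_coded", "uniprot_annotated", "blast_assigned"})

#: required columns per knowledge-base table
_KB_SCHEMA = {
    "organisms": ("organism_id", "genus", "source"),
    "orthologs": ("organism_id", "ko_id"),
    "enzymes": ("organism_id", "ec_number"),
    "ko2rxn": ("ko_id", "reaction_id"),
    "ec2rxn": ("ec_number", "reaction_id"),
    "rpairs": ("reaction_id", "substrate_compound_id", "product_compound_id"),
    "compounds": ("compound_id", "name", "monoisotopic_mass"),
}


class KnowledgeBaseFormatError(ValueError):
    """Raised when a knowledge-base table violates the declared TSV dialect."""


def normalize_genus(label: str) -> str:
    """Canonical genus key: whitespace-trimmed, case-insensitive."""
    return str(label).strip().casefold()


@dataclass
class KnowledgeBase:
    """Organism-to-reaction-to-compound linkage tables.

    Attributes
    ----------
    organisms
        DataFrame indexed by organism id with columns ``genus`` and
        ``source`` (one of ``kegg_coded``, ``uniprot_annotated``,
        ``blast_assigned``).
    ortholog_assignments, enzyme_assignments
        organism id -> set of KO ids / EC numbers.
    ortholog_to_reaction, enzyme_to_reaction
        KO id / EC number -> set of reaction ids.
    reaction_pairs
        reaction id -> set of (substrate, product) compound-id pairs
        (the reaction's primary substrate-product pairs).
    compounds
        DataFrame indexed by compound id with ``name`` and
        ``monoisotopic_mass`` (Da; NaN when unknown).
    diagnostics
        Rows whose cross-references could not be resolved, kept for
        reporting rather than silently dropped.
    """

    organisms: pd.DataFrame
    ortholog_assignments: dict[str, set[str]] = field(default_factory=dict)
    enzyme_assignments: dict[str, set[str]] = field(default_factory=dict)
    ortholog_to_reaction: dict[str, set[str]] = field(default_factory=dict)
    enzyme_to_reaction: dict[str, set[str]] = field(default_factory=dict)
    reaction_pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    compounds: pd.DataFrame | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.organisms.index.has_duplicates:
            dups = self.organisms.index[self.organisms.index.duplicated()].unique()
            raise KnowledgeBaseFormatError(f"duplicate organism id(s): {sorted(dups)}")
        bad = set(self.organisms["source"]) - SOURCE_TAGS
        if bad:
            raise KnowledgeBaseFormatError(
                f"unknown source tag(s) {sorted(bad)}; expected one of {sorted(SOURCE_TAGS)}"
            )
        if self.compounds is not None and len(self.compounds):
            mass = self.compounds["monoisotopic_mass"].dropna()
            if (mass <= 0).any():
                bad_ids = mass.index[mass <= 0].tolist()
                raise KnowledgeBaseFormatError(f"non-positive compound mass for {bad_ids}")

    # -- convenience views ------------------------------------------------

    @property
    def linked_reactions(self) -> set[str]:
        """Reactions reachable from at least one KO or EC link."""
        out: set[str] = set()
        for rxns in self.ortholog_to_reaction.values():
            out |= rxns
        for rxns in self.enzyme_to_reaction.values():
            out |= rxns
        return out

    @property
    def unlinked_pair_reactions(self) -> set[str]:
        """Reactions that have substrate-product pairs but no KO/EC route."""
        return set(self.reaction_pairs) - self.linked_reactions

    def reactions_of_organism(self, organism_id: str) -> set[str]:
        """Union of reactions reachable via the organism's KOs and ECs."""
        rxns: set[str] = set()
        for ko in self.ortholog_assignments.get(organism_id, ()):
            rxns |= self.ortholog_to_reaction.get(ko, set())
        for ec in self.enzyme_assignments.get(organism_id, ()):
            rxns |= self.enzyme_to_reaction.get(ec, set())
        return rxns

    def organisms_of_genus(self, genus: str) -> list[str]:
        key = normalize_genus(genus)
        norm = self.organisms["genus"].map(normalize_genus)
        return self.organisms.index[norm == key].tolist()

    def compound_mass(self, compound_id: str) -> float | None:
        if self.compounds is None or compound_id not in self.compounds.index:
            return None
        m = self.compounds.at[compound_id, "monoisotopic_mass"]
        return None if pd.isna(m) else float(m)


def _read_table(path: str, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _KB_SCHEMA[name]:
        if col not in df.columns:
            raise KnowledgeBaseFormatError(f"{path}: missing required column '{col}'")
    return df


def load_knowledge_base(paths: Mapping[str, str] | str) -> KnowledgeBase:
    """Load a knowledge base from its flat TSV tables.

    Parameters
    ----------
    paths
        Either a directory containing ``organisms.tsv``, ``orthologs.tsv``,
        ``enzymes.tsv``, ``ko2rxn.tsv``, ``ec2rxn.tsv``, ``rpairs.tsv`` and
        ``compounds.tsv``, or a mapping from those table names (sans
        extension) to file paths.  ``organisms`` is required; the rest may be
        absent, yielding an empty linkage for that table.

    Rows whose organism / KO / EC cross-references are unknown are recorded
    in :attr:`KnowledgeBase.diagnostics` and excluded from the linkage maps.
    """
    if isinstance(paths, (str, os.PathLike)):
        root = str(paths)
        paths = {
            name: os.path.join(root, f"{name}.tsv")
            for name in _KB_SCHEMA
            if os.path.exists(os.path.join(root, f"{name}.tsv"))
        }
    if "organisms" not in paths:
        raise KnowledgeBaseFormatError("organisms table is required")

    org_df = _read_table(paths["organisms"], "organisms")
    org_df["genus"] = org_df["genus"].str.strip()
    organisms = org_df.set_index("organism_id")[["genus", "source"]]

    diagnostics: list[str] = []
    known_orgs = set(organisms.index)

    def collect(name: str, key_col: str, val_col: str,
                known_keys: set[str] | None) -> dict[str, set[str]]:
        mapping: dict[str, set[str]] = {}
        if name not in paths:
            return mapping
        df = _read_table(paths[name], name)
        for key, val in zip(df[key_col], df[val_col]):
            if known_keys is not None and key not in known_keys:
                diagnostics.append(f"{name}: unknown {key_col} '{key}' (row dropped)")
                continue
            mapping.setdefault(key, set()).add(val)
        return mapping

    ko_assign = collect("orthologs", "organism_id", "ko_id", known_orgs)
    ec_assign = collect("enzymes", "organism_id", "ec_number", known_orgs)
    known_kos = {ko for s in ko_assign.values() for ko in s} or None
    known_ecs = {ec for s in ec_assign.values() for ec in s} or None
    ko2rxn = collect("ko2rxn", "ko_id", "reaction_id", None)
    ec2rxn = collect("ec2rxn", "ec_number", "reaction_id", None)
    # cross-reference check is informational: a ko2rxn row whose KO no organism
    # carries is legal (the KB may be broader than the community) but noted
    if known_kos is not None:
        for ko in set(ko2rxn) - known_kos:
            diagnostics.append(f"ko2rxn: ko_id '{ko}' assigned to no organism")
    if known_ecs is not None:
        for ec in set(ec2rxn) - known_ecs:
            diagnostics.append(f"ec2rxn: ec_number '{ec}' assigned to no organism")

    reaction_pairs: dict[str, set[tuple[str, str]]] = {}
    if "rpairs" in paths:
        df = _read_table(paths["rpairs"], "rpairs")
        for rxn, sub, prod in zip(
            df["reaction_id"], df["substrate_compound_id"], df["product_compound_id"]
        ):
            reaction_pairs.setdefault(rxn, set()).add((sub, prod))

    compounds = None
    if "compounds" in paths:
        cdf = _read_table(paths["compounds"], "compounds")
        cdf["monoisotopic_mass"] = pd.to_numeric(cdf["monoisotopic_mass"], errors="coerce")
        compounds = cdf.set_index("compound_id")[["name", "monoisotopic_mass"]]

    kb = KnowledgeBase(
        organisms=organisms,
        ortholog_assignments=ko_assign,
        enzyme_assignments=ec_assign,
        ortholog_to_reaction=ko2rxn,
        enzyme_to_reaction=ec2rxn,
        reaction_pairs=reaction_pairs,
        compounds=compounds,
        diagnostics=diagnostics,
    )
    for rxn in sorted(kb.unlinked_pair_reactions):
        diagnostics.append(f"rpairs: reaction '{rxn}' has no KO/EC route (unlinked)")
    return kb


@dataclass
class ORMatrix:
    """Binary genus x reaction presence matrix with per-entry provenance.

    ``values`` is a reactions x genera DataFrame of 0/1.  Entry
    ``(reaction, genus)`` is 1 iff at least one non-excluded organism of the
    genus reaches the reaction via its KO or EC assignments.  ``provenance``
    records which annotation sources (kegg_coded / uniprot_annotated /
    blast_assigned) contributed each 1.  ``uncovered_genera`` lists genera
    with no annotated (non-excluded) organism in the knowledge base — the
    "no annotated genome" report.
    """

    values: pd.DataFrame
    provenance: dict[tuple[str, str], set[str]]
    uncovered_genera: list[str]

    @property
    def genera(self) -> list[str]:
        return list(self.values.columns)

    @property
    def reactions(self) -> list[str]:
        return list(self.values.index)

    def reactions_of_genus(self, genus: str) -> set[str]:
        col = self.values[genus]
        return set(col.index[col == 1])


def build_or_matrix(
    kb: KnowledgeBase,
    genera: Iterable[str],
    exclusions: Iterable[str] = (),
) -> ORMatrix:
    """Assemble the combined genus-reaction matrix from all annotation routes.

    KEGG-coded, UniProt-annotated and BLAST-assigned organisms contribute by
    set union: a genus carries a reaction if any of its member organisms does,
    via either its ortholog or its enzyme assignments.  ``exclusions`` holds
    organism ids removed before the union — the stand-in for manual curation
    of organisms implausible in the habitat under study.
    """
    genera = list(genera)
    if not genera:
        raise ValueError("genera must be non-empty")
    keys = [normalize_genus(g) for g in genera]
    if len(set(keys)) != len(keys):
        seen, dups = set(), []
        for g, k in zip(genera, keys):
            if k in seen:
                dups.append(g)
            seen.add(k)
        raise ValueError(f"duplicate genus label(s): {dups}")
    exclusions = set(exclusions)

    org_genus = kb.organisms["genus"].map(normalize_genus)
    provenance: dict[tuple[str, str], set[str]] = {}
    genus_reactions: dict[str, set[str]] = {g: set() for g in genera}
    uncovered: list[str] = []
    for genus, key in zip(genera, keys):
        members = [
            o for o in kb.organisms.index[org_genus == key] if o not in exclusions
        ]
        if not members:
            uncovered.append(genus)
            continue
        hit = False
        for org in members:
            rxns = kb.reactions_of_organism(org)
            if rxns:
                hit = True
            source = kb.organisms.at[org, "source"]
            for rxn in rxns:
                genus_reactions[genus].add(rxn)
                provenance.setdefault((rxn, genus), set()).add(source)
        if not hit:
            uncovered.append(genus)

    all_reactions = sorted({r for s in genus_reactions.values() for r in s})
    values = pd.DataFrame(0, index=all_reactions, columns=genera, dtype=np.int8)
    for genus, rxns in genus_reactions.items():
        if rxns:
            values.loc[sorted(rxns), genus] = 1
    return ORMatrix(values=values, provenance=provenance, uncovered_genera=uncovered)


@dataclass
class GenusMetaboliteMap:
    """genus label -> set of compound ids the genus can act on.

    A genus "can act on" every compound appearing on either side of a primary
    substrate-product pair of any reaction the genus carries; the pairs are
    treated as unordered for capability purposes.
    """

    mapping: dict[str, set[str]]
    reactions_without_pairs: int = 0

    def __getitem__(self, genus: str) -> set[str]:
        return self.mapping.get(genus, set())

    def can_act_on(self, genus: str, compound_id: str) -> bool:
        return compound_id in self.mapping.get(genus, set())


def derive_genus_metabolite_map(or_matrix: ORMatrix, kb: KnowledgeBase) -> GenusMetaboliteMap:
    """Map each genus to the compounds of its reactions' substrate-product pairs."""
    mapping: dict[str, set[str]] = {}
    no_pairs: set[str] = set()
    for genus in or_matrix.genera:
        compounds: set[str] = set()
        for rxn in or_matrix.reactions_of_genus(genus):
            pairs = kb.reaction_pairs.get(rxn)
            if not pairs:
                no_pairs.add(rxn)
                continue
            for sub, prod in pairs:
                compounds.add(sub)
                compounds.add(prod)
        mapping[genus] = compounds
    return GenusMetaboliteMap(mapping=mapping, reactions_without_pairs=len(no_pairs))


@dataclass
class CoverageReport:
    """How much of the observed community the capability model represents."""

    covered_count_fraction: float
    covered_genera: list[str]
    uncovered_genera: list[str]
    #: reaction id -> number of genera carrying it
    genera_per_reaction: pd.Series
    n_single_genus_reactions: int
    n_ubiquitous_reactions: int
    #: compound id -> fraction of covered genera able to act on it
    metabolite_ubiquity: pd.Series


def model_coverage(
    or_matrix: ORMatrix,
    genus_counts: Mapping[str, float],
    metabolite_map: GenusMetaboliteMap | None = None,
) -> CoverageReport:
    """Fraction of genus-level counts carried by genera the model covers.

    A genus counts as covered when its matrix column has at least one nonzero
    entry.  Also reports, per reaction, how many genera carry it (flagging
    reactions private to a single genus and reactions ubiquitous across all
    genera), and, when a metabolite map is supplied, each compound's
    genus-ubiquity fraction.
    """
    total = float(sum(genus_counts.values()))
    if total <= 0:
        raise ValueError("total genus count is zero; coverage undefined")
    colsums = or_matrix.values.sum(axis=0)
    covered = [g for g in or_matrix.genera if colsums[g] > 0]
    uncovered = [g for g in or_matrix.genera if colsums[g] == 0]
    covered_keys = {normalize_genus(g) for g in covered}
    covered_total = sum(
        c for g, c in genus_counts.items() if normalize_genus(g) in covered_keys
    )
    genera_per_reaction = or_matrix.values.sum(axis=1)
    n_genera = len(or_matrix.genera)
    ubiquity = pd.Series(dtype=float)
    if metabolite_map is not None and covered:
        all_compounds = sorted({c for s in metabolite_map.mapping.values() for c in s})
        ubiquity = pd.Series(
            {
                c: sum(1 for g in covered if c in metabolite_map[g]) / len(covered)
                for c in all_compounds
            },
            dtype=float,
        )
    return CoverageReport(
        covered_count_fraction=covered_total / total,
        covered_genera=covered,
        uncovered_genera=uncovered,
        genera_per_reaction=genera_per_reaction,
        n_single_genus_reactions=int((genera_per_reaction == 1).sum()),
        n_ubiquitous_reactions=int((genera_per_reaction == n_genera).sum()),
        metabolite_ubiquity=ubiquity,
    )
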