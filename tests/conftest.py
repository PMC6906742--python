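"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately re-derive results by naive enumeration
(nested-loop joins, exhaustive traversal) so they stay independent of the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ceconet.knowledge import KnowledgeBase, ORMatrix, load_knowledge_base


# ---------------------------------------------------------------------------
# hand-written tiny knowledge base


TINY_KB_TABLES = {
    "organisms": [
        ("organism_id", "genus", "source"),
        ("lacto_1", "Lactobacillus", "kegg_coded"),
        ("lacto_2", "Lactobacillus", "uniprot_annotated"),
        ("clostr_1", "Clostridium", "blast_assigned"),
        ("alist_1", "Alistipes", "kegg_coded"),
        ("entero_1", "Enterococcus", "kegg_coded"),
    ],
    "orthologs": [
        ("organism_id", "ko_id"),
        ("lacto_1", "K00016"),
        ("lacto_2", "K00016"),
        ("clostr_1", "K01667"),
        ("alist_1", "K00657"),
        ("entero_1", "K05septic"),
    ],
    "enzymes": [
        ("organism_id", "ec_number"),
        ("lacto_1", "1.1.1.27"),
        ("alist_1", "2.3.1.57"),
    ],
    "ko2rxn": [
        ("ko_id", "reaction_id"),
        ("K00016", "R00703"),
        ("K01667", "R00673"),
        ("K00657", "R01154"),
    ],
    "ec2rxn": [
        ("ec_number", "reaction_id"),
        ("1.1.1.27", "R00703"),
        ("2.3.1.57", "R01154"),
        ("2.3.1.57", "R09410"),
    ],
    "rpairs": [
        ("reaction_id", "substrate_compound_id", "product_compound_id"),
        ("R00703", "C00022", "C00186"),
        ("R00673", "C00078", "C00463"),
        ("R01154", "C00134", "C02714"),
        ("R09410", "C00134", "C18174"),
    ],
    "compounds": [
        ("compound_id", "name", "monoisotopic_mass"),
        ("C00022", "pyruvate", "88.01604"),
        ("C00186", "lactate", "90.03169"),
        ("C00078", "tryptophan", "204.08988"),
        ("C00463", "indole", "117.05785"),
        ("C00134", "putrescine", "88.10005"),
        ("C02714", "N-acetylputrescine", "130.11061"),
        ("C18174", "decoy-acetylputrescine", ""),
    ],
}


def write_tiny_kb(root) -> str:
    for name, rows in TINY_KB_TABLES.items():
        with open(root / f"{name}.tsv", "w") as fh:
            for row in rows:
                fh.write("\t".join(row) + "\n")
    return str(root)


@pytest.fixture(scope="session")
def tiny_kb_dir(tmp_path_factory) -> str:
    return write_tiny_kb(tmp_path_factory.mktemp("tiny_kb"))


@pytest.fixture(scope="session")
def tiny_kb(tiny_kb_dir) -> KnowledgeBase:
    return load_knowledge_base(tiny_kb_dir)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_genus_reactions(
    kb: KnowledgeBase, genus: str, exclusions: set[str] = frozenset()
) -> set[str]:
    """Exhaustive organism -> KO/EC -> reaction path enumeration."""
    target = genus.strip().casefold()
    reached: set[str] = set()
    for org in kb.organisms.index:
        if org in exclusions:
            continue
        if kb.organisms.at[org, "genus"].strip().casefold() != target:
            continue
        for ko in kb.ortholog_assignments.get(org, set()):
            for rxn in kb.ortholog_to_reaction.get(ko, set()):
                reached.add(rxn)
        for ec in kb.enzyme_assignments.get(org, set()):
            for rxn in kb.enzyme_to_reaction.get(ec, set()):
                reached.add(rxn)
    return reached


def brute_force_genus_compounds(
    kb: KnowledgeBase, genus: str, exclusions: set[str] = frozenset()
) -> set[str]:
    """Exhaustive organism -> reaction -> substrate-product pair traversal."""
    compounds: set[str] = set()
    for rxn in brute_force_genus_reactions(kb, genus, exclusions):
        for sub, prod in kb.reaction_pairs.get(rxn, set()):
            compounds.add(sub)
            compounds.add(prod)
    return compounds


def brute_force_or_matrix(
    kb: KnowledgeBase, genera: list[str], exclusions: set[str] = frozenset()
) -> dict[tuple[str, str], int]:
    """(reaction, genus) -> 0/1 by exhaustive traversal."""
    out: dict[tuple[str, str], int] = {}
    all_rxns = set(kb.reaction_pairs) | kb.linked_reactions
    for genus in genera:
        reached = brute_force_genus_reactions(kb, genus, exclusions)
        for rxn in all_rxns:
            out[(rxn, genus)] = 1 if rxn in reached else 0
    return out


def assert_matches_brute_force(
    or_matrix: ORMatrix, kb: KnowledgeBase, exclusions: set[str] = frozenset()
) -> None:
    oracle = brute_force_or_matrix(kb, or_matrix.genera, exclusions)
    for (rxn, genus), val in oracle.items():
        got = (
            int(or_matrix.values.at[rxn, genus])
            if rxn in or_matrix.values.index
            else 0
        )
        assert got == val, f"mismatch at ({rxn}, {genus}): got {got}, oracle {val}"


def naive_bh(pvals: np.ndarray) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg step-up, written as explicit loops."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        best = np.inf
        for j in range(i, m):
            cand = sorted_p[j] * m / (j + 1)
            if cand < best:
                best = cand
        q_sorted[i] = min(best, 1.0)
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = q_sorted[i]
    return q


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Definitional Pearson r plus a numeric t-tail integral for p."""
    from scipy.integrate import quad

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    r = num / den
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t_obs = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    df = n - 2
    from scipy.special import gammaln

    log_c = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)

    def pdf(t):
        return np.exp(log_c - (df + 1) / 2 * np.log1p(t * t / df))

    tail, _ = quad(pdf, t_obs, np.inf, epsabs=1e-14, epsrel=1e-12)
    return float(r), float(2.0 * tail)
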