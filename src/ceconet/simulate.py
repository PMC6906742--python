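"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design the pipeline targets: an anaerobic batch culture of
a murine cecal community sampled at days 1 and 7, five replicate cultures per
treatment arm (vehicle control plus a low and a high phthalate dose),
uninoculated-medium blanks, genus-level abundance shifts between days,
metabolite peak areas with planted genus-metabolite correlations (some
genome-supported, some purely empirical), five temporal feature classes,
isotopologue ladders, and a dose-dependent parent-to-monoester degradation
feature pair.  Every generator is reproducible bit-for-bit under a fixed
seed, and the emitted tables use exactly the TSV dialects the other modules
consume.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge import KnowledgeBase, load_knowledge_base
from .profiles import GenusProfile, OtuTable, aggregate_to_genus
from .features import PROTON_MASS, ISOTOPE_SPACING, PeakList

__all__ = [
    "GroundTruth",
    "generate_knowledge_base",
    "generate_community",
    "generate_features",
    "simulate_planted_screen",
    "write_peak_lists",
    "write_otu_table",
]

DOSE_OF_TREATMENT = {"control": 0.0, "low": 10.0, "high": 100.0}


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    seed: int
    params: dict = field(default_factory=dict)
    #: (genus, compound id) capability plants in the knowledge base
    planted_capabilities: list[tuple[str, str]] = field(default_factory=list)
    unannotated_genera: list[str] = field(default_factory=list)
    #: planted correlations: genus, compound_id, true r, mechanistic flag
    planted_pairs: list[dict] = field(default_factory=list)
    #: theoretical feature m/z -> planted temporal class
    planted_classes: dict[float, str] = field(default_factory=dict)
    #: each ladder is the list of rung m/z values (monoisotopic first)
    ladders: list[list[float]] = field(default_factory=list)
    dose_response: dict | None = None
    #: samples x compound-id latent metabolite signals (not serialized)
    metabolite_signals: pd.DataFrame | None = None

    def to_json(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d.pop("metabolite_signals")
        d["planted_classes"] = {f"{k:.6f}": v for k, v in self.planted_classes.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# knowledge base


def generate_knowledge_base(
    out_dir: str,
    n_genera: int = 10,
    n_organisms_per_genus: int = 2,
    n_reactions: int = 50,
    n_compounds: int = 40,
    frac_unannotated_genera: float = 0.2,
    n_planted_capabilities: int = 5,
    seed: int = 0,
) -> tuple[KnowledgeBase, GroundTruth]:
    """Emit a random but reproducible knowledge base as TSV tables.

    ``frac_unannotated_genera`` of the genera get no organisms at all (the
    analogue of genera without an annotated genome).  For
    ``n_planted_capabilities`` designated (genus, compound) pairs a dedicated
    reaction, ortholog and organism assignment guarantee the capability, so
    mechanistic-edge recovery can be checked against ground truth.
    """
    if min(n_genera, n_organisms_per_genus, n_reactions, n_compounds) < 1:
        raise ValueError("all counts must be >= 1")
    if not (0.0 <= frac_unannotated_genera < 1.0):
        raise ValueError("frac_unannotated_genera must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    genera = [f"Genus{i + 1:02d}" for i in range(n_genera)]
    n_unann = int(round(frac_unannotated_genera * n_genera))
    unannotated = (
        [str(g) for g in rng.choice(genera, size=n_unann, replace=False)] if n_unann else []
    )
    annotated = [g for g in genera if g not in set(unannotated)]
    if not annotated:
        raise ValueError("all genera unannotated; infeasible")
    if n_planted_capabilities > 0 and n_planted_capabilities > len(annotated):
        raise ValueError("more capability plants than annotated genera")

    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    masses = rng.uniform(80.0, 600.0, size=n_compounds)
    reactions = [f"R{i + 1:04d}" for i in range(n_reactions)]
    kos = [f"K{i + 1:05d}" for i in range(n_reactions)]
    n_ec = max(1, n_reactions // 3)
    ecs = [f"{rng.integers(1, 7)}.{i % 9 + 1}.{i % 5 + 1}.{i + 1}" for i in range(n_ec)]

    ko2rxn = [(kos[i], reactions[i]) for i in range(n_reactions)]
    ec2rxn = [(ecs[i % n_ec], reactions[i]) for i in rng.choice(n_reactions, size=n_ec, replace=False)]

    rpairs = []
    for rxn in reactions:
        n_pairs = int(rng.integers(1, 3))
        for _ in range(n_pairs):
            sub, prod = rng.choice(n_compounds, size=2, replace=False)
            rpairs.append((rxn, compounds[sub], compounds[prod]))

    organisms = []
    org_kos: list[tuple[str, str]] = []
    org_ecs: list[tuple[str, str]] = []
    sources = ["kegg_coded", "uniprot_annotated", "blast_assigned"]
    for genus in annotated:
        for j in range(n_organisms_per_genus):
            org = f"{genus.lower()}_org{j + 1}"
            organisms.append((org, genus, sources[int(rng.integers(0, 3))]))
            for ko in rng.choice(kos, size=int(rng.integers(2, 8)), replace=False):
                org_kos.append((org, str(ko)))
            if rng.random() < 0.5:
                for ec in rng.choice(ecs, size=int(rng.integers(1, 3)), replace=False):
                    org_ecs.append((org, str(ec)))

    # capability plants: dedicated reaction + KO + assignment per (genus, compound)
    planted: list[tuple[str, str]] = []
    plant_genera = [str(g) for g in rng.choice(annotated, size=n_planted_capabilities, replace=False)]
    plant_compounds = [str(c) for c in rng.choice(compounds, size=n_planted_capabilities, replace=False)]
    for i, (genus, comp) in enumerate(zip(plant_genera, plant_compounds)):
        rxn = f"RP{i + 1:03d}"
        ko = f"KP{i + 1:04d}"
        partner = compounds[int(rng.integers(0, n_compounds))]
        ko2rxn.append((ko, rxn))
        rpairs.append((rxn, comp, partner))
        org_kos.append((f"{genus.lower()}_org1", ko))
        planted.append((genus, comp))

    os.makedirs(out_dir, exist_ok=True)

    def write(name: str, header: list[str], rows: list[tuple]) -> None:
        with open(os.path.join(out_dir, f"{name}.tsv"), "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in sorted(rows):
                fh.write("\t".join(str(x) for x in row) + "\n")

    write("organisms", ["organism_id", "genus", "source"], organisms)
    write("orthologs", ["organism_id", "ko_id"], sorted(set(org_kos)))
    write("enzymes", ["organism_id", "ec_number"], sorted(set(org_ecs)))
    write("ko2rxn", ["ko_id", "reaction_id"], sorted(set(ko2rxn)))
    write("ec2rxn", ["ec_number", "reaction_id"], sorted(set(ec2rxn)))
    write("rpairs", ["reaction_id", "substrate_compound_id", "product_compound_id"],
          sorted(set(rpairs)))
    write("compounds", ["compound_id", "name", "monoisotopic_mass"],
          [(c, f"compound {c}", f"{m:.5f}") for c, m in zip(compounds, masses)])

    truth = GroundTruth(
        seed=int(seed),
        params={
            "n_genera": n_genera,
            "n_organisms_per_genus": n_organisms_per_genus,
            "n_reactions": n_reactions,
            "n_compounds": n_compounds,
            "frac_unannotated_genera": frac_unannotated_genera,
        },
        planted_capabilities=planted,
        unannotated_genera=sorted(unannotated),
    )
    return load_knowledge_base(out_dir), truth


# ---------------------------------------------------------------------------
# community


def generate_community(
    kb: KnowledgeBase,
    truth: GroundTruth,
    n_replicates: int = 5,
    days: tuple[int, ...] = (1, 7),
    treatments: tuple[str, ...] = ("control", "low", "high"),
    planted_r: float = 0.95,
    n_empirical_pairs: int = 2,
    noise_sd: float = 1.0,
    depth: int = 50_000,
    otus_per_genus: int = 2,
    seed: int = 0,
) -> tuple[OtuTable, GenusProfile, GroundTruth]:
    """Simulate genus abundance profiles and planted metabolite signals.

    Genus abundances are log-normal with genus-specific day effects (so some
    genera shift markedly between days 1 and 7, as real cultures do).  OTU
    counts are multinomial at ``depth`` per sample.  For every capability
    pair planted in the knowledge base, plus ``n_empirical_pairs`` pairs
    involving compounds the genus can NOT act on, a latent metabolite signal
    is built as a linear transform of the genus's (latent) relative abundance
    plus Gaussian noise scaled so that the population correlation equals
    ``planted_r`` when ``noise_sd`` is 1; ``noise_sd = 0`` gives an exact
    linear transform (sample r = +/-1).
    """
    if len(days) * len(treatments) * n_replicates < 3:
        raise ValueError("need at least 3 inoculated samples")
    if not (-1.0 < planted_r < 1.0) or planted_r == 0.0:
        raise ValueError(f"planted r = {planted_r} cannot be calibrated")
    rng = np.random.default_rng(seed)

    genera = sorted(set(kb.organisms["genus"])) + sorted(truth.unannotated_genera)
    n_genera = len(genera)

    sample_rows = []
    for day in days:
        for trt in treatments:
            for rep in range(1, n_replicates + 1):
                sample_rows.append(
                    (f"d{day}_{trt}_r{rep}", day, trt, DOSE_OF_TREATMENT[trt], rep, True)
                )
        for rep in range(1, n_replicates + 1):
            sample_rows.append((f"d{day}_blank_b{rep}", day, "blank", 0.0, rep, False))
    metadata = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "day", "treatment", "dose_uM", "replicate", "inoculated"],
    ).set_index("sample_id")

    inoc = metadata.index[metadata["inoculated"]]
    base_log = rng.normal(0.0, 1.0, size=n_genera)
    day7_shift = rng.normal(0.0, 0.6, size=n_genera)
    latent = pd.DataFrame(0.0, index=inoc, columns=genera)
    for s in inoc:
        is_d7 = metadata.at[s, "day"] == max(days)
        logs = base_log + (day7_shift if is_d7 else 0.0) + rng.normal(0.0, 0.3, n_genera)
        w = np.exp(logs)
        latent.loc[s] = w / w.sum()

    # OTU counts: each genus split over a few OTUs, multinomial at fixed depth
    otu_ids, lineage_map, probs_cols = [], {}, []
    for g in genera:
        splits = rng.dirichlet(np.ones(otus_per_genus))
        for k in range(otus_per_genus):
            otu = f"OTU_{g}_{k + 1}"
            otu_ids.append(otu)
            lineage_map[otu] = (
                f"k__Bacteria;p__PhylumX;c__ClassX;o__OrderX;f__FamilyX;g__{g}"
            )
            probs_cols.append((g, splits[k]))
    counts = np.zeros((len(inoc), len(otu_ids)), dtype=np.int64)
    for i, s in enumerate(inoc):
        p = np.array([latent.at[s, g] * frac for g, frac in probs_cols])
        counts[i] = rng.multinomial(depth, p / p.sum())
    otu_table = OtuTable(
        counts=pd.DataFrame(counts, index=list(inoc), columns=otu_ids),
        lineages=pd.Series(lineage_map),
        metadata=metadata,
    )
    profile = aggregate_to_genus(otu_table)

    # planted correlation pairs: capability plants are mechanistic by design
    capability_compounds = {c for _, c in truth.planted_capabilities}
    pair_specs: list[tuple[str, str, bool]] = [
        (g, c, True) for g, c in truth.planted_capabilities
    ]
    eligible_genera = [g for g in genera if g not in set(truth.unannotated_genera)]
    all_compounds = list(kb.compounds.index) if kb.compounds is not None else []
    n_added = 0
    for _ in range(20 * n_empirical_pairs):  # rejection-sample genuinely empirical pairs
        if n_added >= n_empirical_pairs:
            break
        g = eligible_genera[int(rng.integers(0, len(eligible_genera)))]
        c = str(all_compounds[int(rng.integers(0, len(all_compounds)))])
        if c in capability_compounds or any(c2 == c for _, c2, _ in pair_specs):
            continue
        reachable = set()
        for org in kb.organisms_of_genus(g):
            for rxn in kb.reactions_of_organism(org):
                for sub, prod in kb.reaction_pairs.get(rxn, set()):
                    reachable.add(sub)
                    reachable.add(prod)
        if c in reachable:
            continue
        pair_specs.append((g, c, False))
        n_added += 1

    signals = pd.DataFrame(0.0, index=list(inoc), columns=[c for _, c, _ in pair_specs])
    planted_pairs = []
    for genus, comp, mech in pair_specs:
        x = latent[genus].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate abundance for genus {genus}")
        u = (x - x.mean()) / x.std()
        sign = 1.0 if planted_r > 0 else -1.0
        noise_scale = noise_sd * np.sqrt(1.0 / planted_r**2 - 1.0)
        v = sign * u + noise_scale * rng.normal(0.0, 1.0, len(u))
        area = 1e4 * np.clip(6.0 + v, 0.05, None)  # keep areas positive
        signals[comp] = area
        planted_pairs.append(
            {"genus": genus, "compound_id": comp, "r": float(np.sign(planted_r) * abs(planted_r)),
             "mechanistic": bool(mech)}
        )

    out_truth = dataclasses.replace(
        truth,
        planted_pairs=planted_pairs,
        metabolite_signals=signals,
    )
    out_truth.params = dict(truth.params)
    out_truth.params.update(
        {
            "n_replicates": n_replicates,
            "days": list(days),
            "treatments": list(treatments),
            "planted_r": planted_r,
            "noise_sd": noise_sd,
            "depth": depth,
        }
    )
    return otu_table, profile, out_truth


# ---------------------------------------------------------------------------
# LC-MS features


def generate_features(
    profile: GenusProfile,
    kb: KnowledgeBase,
    truth: GroundTruth,
    n_per_class: int = 4,
    effect_sd: float = 5.0,
    n_ladders: int = 3,
    ladder_rungs: int = 3,
    dose_response: bool = True,
    n_noise_features: int = 15,
    mode: str = "positive",
    mz_jitter_ppm: float = 1.5,
    rt_jitter_min: float = 0.01,
    seed: int = 0,
) -> tuple[list[PeakList], GroundTruth]:
    """Emit per-sample peak lists realizing the planted structure.

    Contents: (1) one feature per planted correlated compound at its [M+H]+
    (or [M-H]-) m/z whose inoculated-sample intensities follow the calibrated
    latent signal; (2) ``n_per_class`` features for each of the five temporal
    classes, with inoculated-vs-blank group means separated by ``effect_sd``
    within-group standard deviations in the planted directions; (3)
    ``n_ladders`` isotopologue ladders (+1.00336 Da rungs at decaying
    intensity); (4) a dose-dependent parent/monoester pair whose day-7
    monoester intensity scales with dose; (5) unstructured noise features.
    """
    if truth.metabolite_signals is None:
        raise ValueError("community ground truth carries no metabolite signals")
    if profile.metadata is None:
        raise ValueError("profile lacks sample metadata")
    rng = np.random.default_rng(seed)
    md = profile.metadata
    samples = list(md.index)
    inoc = [s for s in samples if md.at[s, "inoculated"]]
    day_of = md["day"].to_dict()

    adduct = PROTON_MASS if mode == "positive" else -PROTON_MASS
    baseline, within_sd = 1000.0, 50.0
    effect = effect_sd * within_sd

    # rows: (theoretical mz, rt, per-sample intensity function)
    specs: list[tuple[float, float, dict[str, float]]] = []
    used_mz: list[float] = []

    def fresh_mz(mz: float) -> float:
        # avoid accidental 10-ppm collisions between planted features
        while any(abs(mz - u) <= 12e-6 * mz for u in used_mz):
            mz += 0.05
        used_mz.append(mz)
        return mz

    # (1) planted correlated metabolites
    for comp in truth.metabolite_signals.columns:
        mass = kb.compound_mass(comp)
        if mass is None:
            raise ValueError(f"compound {comp} lacks a monoisotopic mass")
        mz = fresh_mz(mass + adduct)
        rt = float(rng.uniform(1.0, 12.0))
        values = {s: baseline + rng.normal(0.0, within_sd) for s in samples}
        for s in inoc:
            values[s] = float(truth.metabolite_signals.at[s, comp])
        specs.append((mz, rt, values))

    # (2) temporal classes
    class_offsets = {
        "fast_substrate": (-effect, -effect),
        "slow_substrate": (0.0, -effect),
        "fast_product": (effect, effect),
        "slow_product": (0.0, effect),
        "intermediate": (effect, 0.0),
    }
    planted_classes: dict[float, str] = {}
    for cls, (off1, off7) in class_offsets.items():
        for _ in range(n_per_class):
            mz = fresh_mz(float(rng.uniform(120.0, 580.0)))
            rt = float(rng.uniform(0.5, 14.0))
            values = {}
            for s in samples:
                off = 0.0
                if md.at[s, "inoculated"]:
                    off = off1 if day_of[s] == 1 else off7
                values[s] = baseline + off + rng.normal(0.0, within_sd)
            specs.append((mz, rt, values))
            planted_classes[mz] = cls

    # (3) isotopologue ladders
    ladders: list[list[float]] = []
    for _ in range(n_ladders):
        m0 = fresh_mz(float(rng.uniform(150.0, 500.0)))
        rt = float(rng.uniform(0.5, 14.0))
        rung_mzs = [m0]
        base_int = float(rng.uniform(2000.0, 8000.0))
        values0 = {s: base_int + rng.normal(0.0, within_sd) for s in samples}
        specs.append((m0, rt, values0))
        for k in range(1, ladder_rungs):
            mk = m0 + k * ISOTOPE_SPACING
            used_mz.append(mk)
            frac = 0.35**k
            values = {s: values0[s] * frac for s in samples}
            specs.append((mk, rt, values))
            rung_mzs.append(mk)
        ladders.append(rung_mzs)

    # (4) dose-response parent -> monoester pair
    dose_truth = None
    if dose_response:
        parent_mz = fresh_mz(391.2843)  # plasticizer-like diester, [M+H]+
        mono_mz = fresh_mz(279.1591)    # its monoester hydrolysis product
        parent_rt, mono_rt = 10.5, 7.8
        parent_vals, mono_vals = {}, {}
        for s in samples:
            dose = float(md.at[s, "dose_uM"]) if md.at[s, "inoculated"] else 0.0
            day = day_of[s]
            # parent spikes in at t0 and is degraded over time
            parent = dose * (800.0 if day == 1 else 150.0)
            mono = dose * (60.0 if day == 1 else 500.0)
            parent_vals[s] = max(0.0, parent * (1 + rng.normal(0, 0.05)))
            mono_vals[s] = max(0.0, mono * (1 + rng.normal(0, 0.05)))
        specs.append((parent_mz, parent_rt, parent_vals))
        specs.append((mono_mz, mono_rt, mono_vals))
        dose_truth = {"parent_mz": parent_mz, "monoester_mz": mono_mz}

    # (5) unstructured noise features
    for _ in range(n_noise_features):
        mz = fresh_mz(float(rng.uniform(100.0, 590.0)))
        rt = float(rng.uniform(0.5, 14.0))
        level = float(rng.uniform(300.0, 5000.0))
        values = {s: level * float(rng.lognormal(0.0, 0.2)) for s in samples}
        specs.append((mz, rt, values))

    peaklists = []
    for s in samples:
        rows = []
        for mz, rt, values in specs:
            inten = values[s]
            if inten <= 0:
                continue  # feature absent in this sample
            jitter = rng.normal(0.0, mz_jitter_ppm) * 1e-6 * mz
            rows.append(
                (mz + jitter, max(0.0, rt + rng.normal(0.0, rt_jitter_min)), inten)
            )
        peaklists.append(
            PeakList(
                sample_id=s,
                mode=mode,
                peaks=pd.DataFrame(rows, columns=["mz", "rt_min", "intensity_cps"]),
            )
        )

    out_truth = dataclasses.replace(
        truth,
        planted_classes=planted_classes,
        ladders=ladders,
        dose_response=dose_truth,
    )
    return peaklists, out_truth


# ---------------------------------------------------------------------------
# low-level screen simulator (for FDR / recovery studies)


def simulate_planted_screen(
    n_genera: int = 20,
    n_metabolites: int = 30,
    n_planted: int = 30,
    true_r: float = 0.95,
    n_samples: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, set[tuple[str, str]]]:
    """Paired genus/metabolite matrices with ``n_planted`` correlated pairs.

    Each planted metabolite is tied to exactly one genus at population
    correlation ``true_r``; all remaining metabolites are independent noise,
    so the ``n_genera * n_metabolites`` pair family contains exactly
    ``n_planted`` true signals.  Intended for false-discovery-rate and
    sensitivity studies of the correlation screen.
    """
    if n_planted > n_metabolites:
        raise ValueError("each planted pair needs its own metabolite")
    rng = np.random.default_rng(seed)
    genera = [f"G{i + 1:03d}" for i in range(n_genera)]
    mets = [f"M{j + 1:03d}" for j in range(n_metabolites)]
    X = rng.normal(size=(n_samples, n_genera))
    Y = rng.normal(size=(n_samples, n_metabolites))
    planted: set[tuple[str, str]] = set()
    if n_planted:
        if not (-1.0 < true_r < 1.0) or true_r == 0.0:
            raise ValueError("true_r must lie in (-1, 0) or (0, 1)")
        noise_scale = np.sqrt(1.0 / true_r**2 - 1.0)
        for j in range(n_planted):
            i = j % n_genera
            Y[:, j] = np.sign(true_r) * X[:, i] + noise_scale * rng.normal(size=n_samples)
            planted.add((genera[i], mets[j]))
    return (
        pd.DataFrame(X, columns=genera, index=[f"s{k}" for k in range(n_samples)]),
        pd.DataFrame(Y, columns=mets, index=[f"s{k}" for k in range(n_samples)]),
        planted,
    )


# ---------------------------------------------------------------------------
# writers for the pipeline's file dialects


def write_otu_table(table: OtuTable, path: str, metadata_path: str | None = None) -> None:
    """Write the OTU matrix TSV (first column OTU id, last column lineage)."""
    df = table.counts.T.copy()
    df.insert(len(df.columns), "lineage", table.lineages.reindex(df.index))
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")
    if metadata_path and table.metadata is not None:
        md = table.metadata.copy()
        md["inoculated"] = md["inoculated"].map({True: "yes", False: "no"})
        md.to_csv(metadata_path, sep="\t")


def write_peak_lists(peaklists: list[PeakList], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmode\tmz\trt_min\tintensity_cps\n")
        for pl in peaklists:
            for mz, rt, inten in zip(
                pl.peaks["mz"], pl.peaks["rt_min"], pl.peaks["intensity_cps"]
            ):
                fh.write(f"{pl.sample_id}\t{pl.mode}\t{mz:.6f}\t{rt:.4f}\t{inten:.3f}\n")
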