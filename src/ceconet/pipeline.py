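"""End-to-end orchestration: knowledge base -> profiles -> features -> network.

A single :class:`RunConfig` (loadable from a YAML file) names the inputs and
every threshold of the analysis; :func:`run_pipeline` executes the stages in
order and writes the network files plus a machine-readable ``report.json``.
Identical config, inputs and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .knowledge import (
    build_or_matrix,
    derive_genus_metabolite_map,
    load_knowledge_base,
    model_coverage,
)
from .profiles import (
    abundance_filter,
    aggregate_to_genus,
    filter_singletons,
    rarefy,
    read_otu_table,
)
from .features import (
    align_peaks,
    annotate_by_mass_and_neighborhood,
    classify_temporal,
    collapse_isotopologues,
    filter_intensity,
    read_peak_lists,
)
from .network import (
    build_network,
    classify_edges,
    export_network,
    node_fold_change,
)

log = logging.getLogger("ceconet")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending entity."""


@dataclass
class RunConfig:
    """All file paths, thresholds and sample-selection rules for one run.

    Thresholds default to the values the analysis was designed around:
    10 ppm / 0.5 min alignment tolerances, 100 cps intensity floor,
    alpha = 0.05 for the temporal t-tests, |r| >= 0.76 and BH-adjusted
    p < 0.05 for network edges, relative-abundance cutoffs of 0.01 % for
    capability-model inclusion and 0.05 % for correlation eligibility.
    """

    # inputs
    kb_dir: str = ""
    otu_table: str = ""
    sample_metadata: str = ""
    peak_lists: str = ""
    exclusions: list[str] = field(default_factory=list)
    out_dir: str = "ceconet_run"
    # OTU processing
    filter_singletons: bool = True
    rarefaction_depth: int | str | None = "min"
    model_abundance_threshold: float = 0.0001
    correlation_abundance_threshold: float = 0.0005
    require_days: list[int] = field(default_factory=lambda: [1, 7])
    # feature processing
    ppm_tol: float = 10.0
    rt_tol_min: float = 0.5
    isotope_rt_tol_min: float = 0.1
    min_intensity_cps: float = 100.0
    alpha: float = 0.05
    # network
    r_min: float = 0.76
    q_max: float = 0.05
    use_raw_p: bool = False
    fold_dead_zone: float = 0.26
    # sample selection for the correlation screen
    correlation_days: list[int] = field(default_factory=lambda: [1, 7])
    correlation_treatments: list[str] | None = None
    inoculated_only: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("kb_dir", "otu_table", "sample_metadata", "peak_lists"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise PipelineError(f"config: {name} path '{path}' does not exist")
        if not (0 < self.model_abundance_threshold < 1):
            raise PipelineError("config: model_abundance_threshold out of range")
        if not (0 < self.correlation_abundance_threshold < 1):
            raise PipelineError("config: correlation_abundance_threshold out of range")
        if not (0 < self.q_max <= 1) or not (0 <= self.r_min <= 1):
            raise PipelineError("config: r_min/q_max out of range")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report.

    Stages: load KB -> organism-reaction matrix -> capability map -> OTU
    filtering / rarefaction / genus aggregation -> peak alignment, intensity
    filter, isotopologue collapse, temporal classification, annotation ->
    all-pairs correlation screen with BH FDR -> edge classification ->
    fold-change directions -> export.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # --- knowledge base & capability model
    kb = _stage("load_kb")(load_knowledge_base)(config.kb_dir)
    table = _stage("read_otu_table")(read_otu_table)(
        config.otu_table, config.sample_metadata
    )
    n_otus_raw = len(table.otus)
    if config.filter_singletons:
        table = filter_singletons(table)
    if config.rarefaction_depth is not None:
        table = _stage("rarefy")(rarefy)(
            table, depth=config.rarefaction_depth, seed=config.seed
        )
    profile = _stage("aggregate")(aggregate_to_genus)(table)

    model_profile = _stage("model_abundance_filter")(abundance_filter)(
        profile, config.model_abundance_threshold, config.require_days
    )
    or_matrix = _stage("or_matrix")(build_or_matrix)(
        kb, model_profile.genera, set(config.exclusions)
    )
    capability = derive_genus_metabolite_map(or_matrix, kb)
    genus_counts = profile.counts.sum(axis=0).to_dict()
    coverage = _stage("coverage")(model_coverage)(or_matrix, genus_counts, capability)
    report["stages"]["model"] = {
        "n_otus_raw": n_otus_raw,
        "n_otus_after_filters": len(table.otus),
        "n_genera_model": len(model_profile.genera),
        "n_genera_covered": len(coverage.covered_genera),
        "uncovered_genera": coverage.uncovered_genera,
        "covered_count_fraction": coverage.covered_count_fraction,
        "n_reactions": len(or_matrix.reactions),
        "n_single_genus_reactions": coverage.n_single_genus_reactions,
    }

    # --- LC-MS features
    peaklists = _stage("read_peaks")(read_peak_lists)(config.peak_lists)
    ft = _stage("align")(align_peaks)(
        peaklists, ppm_tol=config.ppm_tol, rt_tol_min=config.rt_tol_min
    )
    n_aligned = len(ft.feature_ids)
    ft = filter_intensity(ft, config.min_intensity_cps)
    ft = collapse_isotopologues(
        ft, ppm_tol=config.ppm_tol, rt_tol_min=config.isotope_rt_tol_min
    )
    md = table.metadata
    groups = {}
    for day in (1, 7):
        inoc = md.index[(md["day"] == day) & md["inoculated"]].tolist()
        blank = md.index[(md["day"] == day) & ~md["inoculated"]].tolist()
        if len(inoc) >= 2 and len(blank) >= 2:
            groups[day] = (inoc, blank)
    temporal_summary: dict = {}
    if set(groups) == {1, 7}:
        _, temporal_summary = _stage("classify_temporal")(classify_temporal)(
            ft, groups, alpha=config.alpha
        )
    annotations = _stage("annotate")(annotate_by_mass_and_neighborhood)(
        ft, kb, ppm_tol=config.ppm_tol
    )
    ft.to_tsv(os.path.join(config.out_dir, "feature_table.tsv"))
    report["stages"]["features"] = {
        "n_peaks": int(sum(len(pl.peaks) for pl in peaklists)),
        "n_features_aligned": n_aligned,
        "n_features_final": len(ft.feature_ids),
        "temporal_role_percentages": temporal_summary.get("role_percentages", {}),
        "n_features_annotated": sum(1 for c in annotations.values() if c),
    }

    # --- correlation network
    corr_profile = _stage("corr_abundance_filter")(abundance_filter)(
        profile, config.correlation_abundance_threshold, config.require_days
    )
    sel = md.copy()
    if config.inoculated_only:
        sel = sel[sel["inoculated"]]
    if config.correlation_days:
        sel = sel[sel["day"].isin(config.correlation_days)]
    if config.correlation_treatments:
        sel = sel[sel["treatment"].isin(config.correlation_treatments)]
    sample_ids = [s for s in corr_profile.samples if s in set(sel.index)]

    # metabolite areas: one column per annotated compound (most intense feature wins)
    best: dict[str, str] = {}
    for fid, cands in annotations.items():
        if not cands:
            continue
        cid = cands[0].compound_id
        if cid not in best or (
            ft.intensities.loc[fid].max() > ft.intensities.loc[best[cid]].max()
        ):
            best[cid] = fid
    areas = pd.DataFrame(
        {cid: ft.intensities.loc[fid] for cid, fid in sorted(best.items())}
    ).fillna(0.0)
    compound_ids = {cid: cid for cid in areas.columns}

    net = _stage("build_network")(build_network)(
        corr_profile.relative_abundance.loc[sample_ids],
        areas.loc[[s for s in sample_ids if s in areas.index]],
        r_min=config.r_min,
        q_max=config.q_max,
        use_raw_p=config.use_raw_p,
        compound_ids=compound_ids,
    )
    net = classify_edges(net, capability)

    day_means = {}
    for day in (1, 7):
        ids = [s for s in sample_ids if md.at[s, "day"] == day]
        if not ids:
            continue
        gm = corr_profile.relative_abundance.loc[ids].mean(axis=0).to_dict()
        mm = areas.loc[[s for s in ids if s in areas.index]].mean(axis=0).to_dict()
        day_means[day] = {**gm, **mm}
    if set(day_means) == {1, 7}:
        net.fold_changes = node_fold_change(
            day_means[1], day_means[7], dead_zone=config.fold_dead_zone
        )

    tested = net.report["pairs_tested"]
    retained = net.report["edges_retained"]
    net.report.update(
        {
            "pairs_filtered_thresholds": tested - retained,
            "n_correlation_samples": len(sample_ids),
        }
    )
    paths = _stage("export")(export_network)(net, config.out_dir)
    report["stages"]["network"] = net.report
    report["outputs"] = {k: os.path.basename(v) for k, v in paths.items()}

    with open(os.path.join(config.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info(
        "pipeline complete: %d edges (%s mechanistic) from %d tested pairs",
        retained,
        net.report.get("edges_mechanistic", "?"),
        tested,
    )
    return report
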