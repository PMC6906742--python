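"""Untargeted LC-MS feature processing.

Peak lists from individual samples are aligned into a feature table on m/z
(ppm tolerance) and retention time, intensity-filtered, and reduced to
monoisotopic ions by collapsing isotopologue ladders.  Features are then
classified into temporal substrate/product patterns from inoculated-versus-
medium-blank comparisons at two time points, retention-time drift is
corrected by local linear regression against authentic standards, and
candidate compound annotations are scored by how much of the candidate's
reaction-network neighborhood is also detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .knowledge import KnowledgeBase

__all__ = [
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "PeakList",
    "FeatureTable",
    "TemporalClass",
    "AnnotationCandidate",
    "read_peak_lists",
    "align_peaks",
    "filter_intensity",
    "collapse_isotopologues",
    "classify_temporal",
    "correct_retention_time",
    "annotate_by_mass_and_neighborhood",
]

PROTON_MASS = 1.007276  # Da; [M+H]+ / [M-H]- adduct offset
ISOTOPE_SPACING = 1.00336  # Da; 13C-12C mass difference, charge 1 assumed


@dataclass
class PeakList:
    """Ion peaks from one sample in one ionization mode."""

    sample_id: str
    mode: str  # "positive" | "negative"
    peaks: pd.DataFrame  # columns: mz, rt_min, intensity_cps

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown ionization mode '{self.mode}'")
        p = self.peaks
        if len(p):
            if (p["mz"] <= 0).any():
                raise ValueError("m/z values must be positive")
            if (p["rt_min"] < 0).any() or (p["intensity_cps"] < 0).any():
                raise ValueError("negative RT or intensity")


@dataclass
class FeatureTable:
    """Aligned features (consensus m/z, RT, mode) x per-sample intensities."""

    features: pd.DataFrame  # index feature_id; columns mz, rt_min, mode, monoisotopic
    intensities: pd.DataFrame  # features x samples; NaN = not detected
    temporal_class: pd.Series | None = None
    annotations: dict[str, list["AnnotationCandidate"]] = field(default_factory=dict)
    #: per-sample summed intensity of each collapsed isotopologue group
    group_intensities: pd.DataFrame | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def mode(self) -> str:
        modes = set(self.features["mode"])
        if len(modes) != 1:
            raise ValueError(f"feature table mixes ionization modes: {sorted(modes)}")
        return next(iter(modes))

    def to_tsv(self, path: str) -> None:
        out = self.features.copy()
        out = out.join(self.intensities)
        if self.temporal_class is not None:
            out["temporal_class"] = self.temporal_class
        if self.annotations:
            top = {
                fid: (c[0].compound_id if c else "")
                for fid, c in self.annotations.items()
            }
            score = {fid: (c[0].score if c else "") for fid, c in self.annotations.items()}
            out["top_annotation"] = pd.Series(top).reindex(out.index).fillna("")
            out["annotation_score"] = pd.Series(score).reindex(out.index).fillna("")
        out.to_csv(path, sep="\t", index_label="feature_id")


class TemporalClass(str, Enum):
    """Five substrate/product time-course patterns plus a residual class."""

    FAST_SUBSTRATE = "fast_substrate"  # significantly depleted by day 1 and day 7
    SLOW_SUBSTRATE = "slow_substrate"  # depleted only by day 7
    FAST_PRODUCT = "fast_product"      # elevated by day 1 and still at day 7
    SLOW_PRODUCT = "slow_product"      # elevated only by day 7
    INTERMEDIATE = "intermediate"      # elevated by day 1, back down (or gone) by day 7
    UNCLASSIFIED = "unclassified"


@dataclass
class AnnotationCandidate:
    """One candidate compound identity for a feature."""

    compound_id: str
    adduct: str  # "M+H" | "M-H"
    mass_error_ppm: float
    score: int  # detected reaction-pair neighbors
    rank: int = 0


def read_peak_lists(path: str) -> list[PeakList]:
    """Read per-sample peak lists from a TSV with columns
    sample_id, mode, mz, rt_min, intensity_cps."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sample, mode), grp in df.groupby(["sample_id", "mode"], sort=True):
        out.append(
            PeakList(
                sample_id=str(sample),
                mode=str(mode),
                peaks=grp[["mz", "rt_min", "intensity_cps"]].reset_index(drop=True),
            )
        )
    return out


def _ppm_match(mz_a: float, mz_b: float, ppm_tol: float) -> bool:
    # tolerance taken relative to the lower of the two masses
    return abs(mz_a - mz_b) <= ppm_tol * 1e-6 * min(mz_a, mz_b)


def align_peaks(
    peaklists: Iterable[PeakList],
    ppm_tol: float = 10.0,
    rt_tol_min: float = 0.5,
) -> FeatureTable:
    """Merge peaks across samples into consensus features.

    Greedy single-linkage seeded by descending intensity: the most intense
    unassigned peak founds a feature; any peak within ``ppm_tol`` (relative
    to the lower m/z) and ``rt_tol_min`` of the seed joins it.  Each sample
    contributes at most one peak per feature — the most intense wins.
    Consensus m/z and RT are intensity-weighted means over member peaks.
    """
    peaklists = list(peaklists)
    modes = {pl.mode for pl in peaklists}
    if len(modes) > 1:
        raise ValueError(f"peak lists mix ionization modes: {sorted(modes)}")
    mode = next(iter(modes)) if modes else "positive"

    rows = []
    for pl in peaklists:
        for mz, rt, inten in zip(
            pl.peaks["mz"], pl.peaks["rt_min"], pl.peaks["intensity_cps"]
        ):
            rows.append((float(mz), float(rt), float(inten), pl.sample_id))
    # canonical order makes the greedy pass input-order independent
    rows.sort(key=lambda r: (-r[2], r[0], r[1], r[3]))

    seeds: list[tuple[float, float]] = []
    members: list[list[tuple[float, float, float, str]]] = []
    claimed: list[set[str]] = []
    for mz, rt, inten, sample in rows:
        placed = False
        for i, (smz, srt) in enumerate(seeds):
            if _ppm_match(mz, smz, ppm_tol) and abs(rt - srt) <= rt_tol_min:
                if sample not in claimed[i]:
                    members[i].append((mz, rt, inten, sample))
                    claimed[i].add(sample)
                placed = True  # within tolerance of an existing feature
                break
        if not placed:
            seeds.append((mz, rt))
            members.append([(mz, rt, inten, sample)])
            claimed.append({sample})

    samples = sorted({pl.sample_id for pl in peaklists})
    consensus = []
    for grp in members:
        w = np.array([m[2] for m in grp])
        if w.sum() == 0:
            w = np.ones(len(grp))
        mzs = np.array([m[0] for m in grp])
        rts = np.array([m[1] for m in grp])
        consensus.append((float(np.average(mzs, weights=w)), float(np.average(rts, weights=w))))

    order = sorted(range(len(members)), key=lambda i: consensus[i])
    feat_ids = [f"F{k + 1:05d}" for k in range(len(order))]
    features = pd.DataFrame(
        {
            "mz": [consensus[i][0] for i in order],
            "rt_min": [consensus[i][1] for i in order],
            "mode": mode,
            "monoisotopic": False,
        },
        index=feat_ids,
    )
    intens = pd.DataFrame(np.nan, index=feat_ids, columns=samples)
    for fid, i in zip(feat_ids, order):
        for mz, rt, inten, sample in members[i]:
            intens.at[fid, sample] = inten
    return FeatureTable(features=features, intensities=intens)


def filter_intensity(ft: FeatureTable, min_cps: float = 100.0) -> FeatureTable:
    """Drop features whose maximum intensity across samples falls below
    ``min_cps``.  Features exactly at the threshold are retained."""
    keep = ft.intensities.max(axis=1).fillna(0) >= min_cps
    return FeatureTable(
        features=ft.features.loc[keep],
        intensities=ft.intensities.loc[keep],
        temporal_class=ft.temporal_class[keep] if ft.temporal_class is not None else None,
        annotations={k: v for k, v in ft.annotations.items() if keep.get(k, False)},
        group_intensities=(
            ft.group_intensities.loc[keep] if ft.group_intensities is not None else None
        ),
    )


def collapse_isotopologues(
    ft: FeatureTable,
    ppm_tol: float = 10.0,
    rt_tol_min: float = 0.1,
    max_rungs: int = 3,
) -> FeatureTable:
    """Represent each isotopologue ladder by its monoisotopic (lowest-mass) member.

    Features co-eluting within ``rt_tol_min`` whose m/z values sit on the
    ladder m0 + k * 1.00336 Da (k = 1..``max_rungs``, each rung within
    ``ppm_tol``) are collapsed onto the lowest-mass member, which is flagged
    monoisotopic.  The summed per-sample intensity of each collapsed group is
    recorded in ``group_intensities``; the survivor's own intensities are
    left untouched.
    """
    feats = ft.features.sort_values(["mz", "rt_min"])
    ids = list(feats.index)
    mz = feats["mz"].to_dict()
    rt = feats["rt_min"].to_dict()
    consumed: set[str] = set()
    groups: dict[str, list[str]] = {}

    for fid in ids:
        if fid in consumed:
            continue
        group = [fid]
        for k in range(1, max_rungs + 1):
            expected = mz[fid] + k * ISOTOPE_SPACING
            cands = [
                g
                for g in ids
                if g not in consumed
                and g != fid
                and abs(rt[g] - rt[fid]) <= rt_tol_min
                and abs(mz[g] - expected) <= ppm_tol * 1e-6 * expected
            ]
            if not cands:
                break  # ladders are contiguous; a gap ends the series
            rung = min(cands, key=lambda g: abs(mz[g] - expected))
            group.append(rung)
            consumed.add(rung)
        groups[fid] = group

    keep = [fid for fid in ft.features.index if fid not in consumed]
    features = ft.features.loc[keep].copy()
    features["monoisotopic"] = True
    group_int = pd.DataFrame(
        {
            fid: ft.intensities.loc[groups[fid]].sum(axis=0, min_count=1)
            for fid in keep
        }
    ).T
    group_int.columns = ft.intensities.columns
    return FeatureTable(
        features=features,
        intensities=ft.intensities.loc[keep],
        temporal_class=ft.temporal_class[keep] if ft.temporal_class is not None else None,
        annotations={k: v for k, v in ft.annotations.items() if k in set(keep)},
        group_intensities=group_int,
    )


def _signed_significance(
    inoc: np.ndarray, blank: np.ndarray, alpha: float
) -> int | None:
    """-1 / 0 / +1 from a two-tailed t-test; None when the test is undefined."""
    if len(inoc) < 2 or len(blank) < 2:
        return None
    if np.ptp(inoc) == 0 and np.ptp(blank) == 0:
        return None if inoc[0] == blank[0] else (1 if inoc[0] > blank[0] else -1)
    t, p = stats.ttest_ind(inoc, blank)
    if np.isnan(p):
        return None
    if p < alpha:
        return 1 if inoc.mean() > blank.mean() else -1
    return 0


_CLASS_RULES: dict[tuple[int, int], TemporalClass] = {
    (-1, -1): TemporalClass.FAST_SUBSTRATE,
    (0, -1): TemporalClass.SLOW_SUBSTRATE,
    (1, 1): TemporalClass.FAST_PRODUCT,
    (0, 1): TemporalClass.SLOW_PRODUCT,
    (1, 0): TemporalClass.INTERMEDIATE,
    (1, -1): TemporalClass.INTERMEDIATE,
}

_ROLE_OF_CLASS = {
    TemporalClass.FAST_SUBSTRATE: "substrate",
    TemporalClass.SLOW_SUBSTRATE: "substrate",
    TemporalClass.FAST_PRODUCT: "product",
    TemporalClass.SLOW_PRODUCT: "product",
    TemporalClass.INTERMEDIATE: "intermediate",
}


def classify_temporal(
    ft: FeatureTable,
    groups: Mapping[int, tuple[Sequence[str], Sequence[str]]],
    alpha: float = 0.05,
) -> tuple[pd.Series, dict]:
    """Assign each feature a temporal substrate/product class.

    ``groups`` maps day (1 and 7) to ``(inoculated sample ids, medium-blank
    sample ids)``.  Per feature and day, a two-tailed t-test of inoculated
    versus blank intensities yields a signed significance (-, 0, +); the
    (day-1, day-7) sign pair is mapped onto the five patterns: depleted at
    both days = fast substrate, depleted only by day 7 = slow substrate,
    elevated at both = fast product, elevated only by day 7 = slow product,
    elevated at day 1 but not day 7 = intermediate.  Undetected intensities
    count as zero.  Returns the per-feature class and a summary with class
    percentages (summing to 100) and the product/substrate/intermediate
    breakdown over classifiable features.
    """
    for day in (1, 7):
        if day not in groups:
            raise ValueError(f"day-{day} group is required")
        for part in groups[day]:
            if len(part) < 2:
                raise ValueError(f"day-{day} groups need >= 2 samples each")

    intens = ft.intensities.fillna(0.0)
    classes: dict[str, str] = {}
    diagnostics: list[str] = []
    for fid in ft.features.index:
        signs = []
        for day in (1, 7):
            inoc_ids, blank_ids = groups[day]
            s = _signed_significance(
                intens.loc[fid, list(inoc_ids)].to_numpy(float),
                intens.loc[fid, list(blank_ids)].to_numpy(float),
                alpha,
            )
            signs.append(s)
        if None in signs:
            classes[fid] = TemporalClass.UNCLASSIFIED.value
            diagnostics.append(f"{fid}: zero-variance group, test undefined")
            continue
        cls = _CLASS_RULES.get((signs[0], signs[1]), TemporalClass.UNCLASSIFIED)
        classes[fid] = cls.value

    series = pd.Series(classes).reindex(ft.features.index)
    n = len(series)
    class_pct = {
        c.value: (100.0 * (series == c.value).sum() / n if n else 0.0)
        for c in TemporalClass
    }
    roles = series.map({k.value: v for k, v in _ROLE_OF_CLASS.items()}).dropna()
    role_pct = (
        {r: 100.0 * (roles == r).sum() / len(roles) for r in ("product", "substrate", "intermediate")}
        if len(roles)
        else {}
    )
    summary = {
        "class_percentages": class_pct,
        "role_percentages": role_pct,
        "n_features": n,
        "diagnostics": diagnostics,
    }
    ft.temporal_class = series
    return series, summary


def correct_retention_time(
    anchors: Sequence[tuple[float, float]],
    query_rts: Sequence[float],
    k: int = 3,
) -> np.ndarray:
    """Map observed retention times onto the pure-standard RT scale.

    ``anchors`` are (observed RT, standard RT) pairs from authentic
    standards.  Each query is corrected by an ordinary least-squares line
    fitted through its ``k`` nearest anchors (by observed RT); queries
    outside the anchor range extrapolate from the nearest window.  This is a
    local linear regression against the standards, compensating
    matrix-induced RT drift.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[0] < 2:
        raise ValueError("need at least 2 (observed, standard) anchor pairs")
    obs, std = anchors[:, 0], anchors[:, 1]
    if len(np.unique(std)) < 2:
        raise ValueError("anchor standard RTs must be distinct")
    k = min(k, len(obs))
    out = np.empty(len(query_rts), dtype=float)
    for i, q in enumerate(np.asarray(query_rts, dtype=float)):
        idx = np.argsort(np.abs(obs - q), kind="stable")[:k]
        x, y = obs[idx], std[idx]
        if np.ptp(x) == 0:  # degenerate window: all anchors at one observed RT
            out[i] = float(np.mean(y))
            continue
        slope, intercept = np.polyfit(x, y, 1)
        out[i] = slope * q + intercept
    return out


def _adduct_mz(mass: float, mode: str) -> float:
    return mass + PROTON_MASS if mode == "positive" else mass - PROTON_MASS


def compound_neighbors(kb: KnowledgeBase) -> dict[str, set[str]]:
    """Compound adjacency at reaction-pair distance 1 (either side of a pair)."""
    adj: dict[str, set[str]] = {}
    for pairs in kb.reaction_pairs.values():
        for sub, prod in pairs:
            adj.setdefault(sub, set()).add(prod)
            adj.setdefault(prod, set()).add(sub)
    return adj


def annotate_by_mass_and_neighborhood(
    ft: FeatureTable,
    kb: KnowledgeBase,
    ppm_tol: float = 10.0,
) -> dict[str, list[AnnotationCandidate]]:
    """Rank candidate compound identities by reaction-network support.

    A compound is a candidate for a feature when its adduct mass (M+H in
    positive mode, M-H in negative) matches the feature's m/z within
    ``ppm_tol``.  Its neighborhood score counts the distinct compounds one
    reaction-pair hop away whose adduct masses match any detected feature.
    Candidates are ranked by score (descending), ties broken by absolute
    mass error — a mass match corroborated by detected neighbors outranks an
    isobaric decoy with none.
    """
    if kb.compounds is None or kb.compounds["monoisotopic_mass"].dropna().empty:
        raise ValueError("knowledge base has no compound masses; cannot annotate")
    mode = ft.mode
    masses = kb.compounds["monoisotopic_mass"].dropna()
    comp_ids = masses.index.to_numpy()
    adduct = "M+H" if mode == "positive" else "M-H"
    adduct_mzs = np.array([_adduct_mz(m, mode) for m in masses.to_numpy(float)])

    detected = np.sort(ft.features["mz"].to_numpy(float))

    def mass_detected(target_mz: float) -> bool:
        j = np.searchsorted(detected, target_mz)
        tol = ppm_tol * 1e-6 * target_mz
        for jj in (j - 1, j):
            if 0 <= jj < len(detected) and abs(detected[jj] - target_mz) <= tol:
                return True
        return False

    adj = compound_neighbors(kb)
    neighbor_score: dict[str, int] = {}

    def score_of(cid: str) -> int:
        if cid not in neighbor_score:
            neighbor_score[cid] = sum(
                1
                for nb in adj.get(cid, ())
                if nb in masses.index and mass_detected(_adduct_mz(float(masses[nb]), mode))
            )
        return neighbor_score[cid]

    out: dict[str, list[AnnotationCandidate]] = {}
    for fid, fmz in zip(ft.features.index, ft.features["mz"].to_numpy(float)):
        tol = ppm_tol * 1e-6 * adduct_mzs
        hits = np.nonzero(np.abs(adduct_mzs - fmz) <= tol)[0]
        cands = []
        for idx in hits:
            cid = str(comp_ids[idx])
            err_ppm = (fmz - adduct_mzs[idx]) / adduct_mzs[idx] * 1e6
            cands.append(
                AnnotationCandidate(
                    compound_id=cid,
                    adduct=adduct,
                    mass_error_ppm=float(err_ppm),
                    score=score_of(cid),
                )
            )
        cands.sort(key=lambda c: (-c.score, abs(c.mass_error_ppm), c.compound_id))
        for rank, c in enumerate(cands, start=1):
            c.rank = rank
        out[fid] = cands
    ft.annotations = out
    return out
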