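"""Segmentation-agreement metrics and the nonparametric comparison battery.

Implements the agreement machinery used to grade FAZ extractions against a
gold standard: pixel-count Jaccard and Dice coefficients, false-negative /
false-positive percentages normalized by the union (so that
``fn% + fp% = (1 - Jaccard) * 100`` holds exactly), magnification-corrected
areas, per-subject between-method coefficients of variation, and a
rank-based comparison battery (Shapiro-Wilk gating, Friedman across methods,
Bonferroni-adjusted pairwise Wilcoxon post-hoc tests, Spearman area
correlations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import ImagingError, RegionMask

#: default reference axial length (mm) of the magnification correction
REFERENCE_AXIAL_LENGTH_MM = 24.2


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, RegionMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ImagingError(f"mask geometry mismatch: {a.shape} vs {b.shape}")
    if not (a.any() or b.any()):
        raise ImagingError("both masks are empty; similarity undefined")


def jaccard(a, b) -> float:
    """Intersection over union of two pixel sets."""
    a, b = _as_bool(a), _as_bool(b)
    _check_pair(a, b)
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union


def dsc(a, b) -> float:
    """Dice similarity coefficient: twice the intersection over the sum of sizes."""
    a, b = _as_bool(a), _as_bool(b)
    _check_pair(a, b)
    inter = np.count_nonzero(a & b)
    return 2.0 * inter / (np.count_nonzero(a) + np.count_nonzero(b))


def fn_fp(target, result) -> Tuple[float, float]:
    """False-negative and false-positive percentages, union-normalized.

    fn% counts target pixels the result missed, fp% counts result pixels
    outside the target, both as percent of |target ∪ result|, so the pair
    sums to (1 - Jaccard) * 100.
    """
    a, b = _as_bool(target), _as_bool(result)
    _check_pair(a, b)
    union = np.count_nonzero(a | b)
    fn = 100.0 * np.count_nonzero(a & ~b) / union
    fp = 100.0 * np.count_nonzero(b & ~a) / union
    return fn, fp


@dataclass
class AreaMeasure:
    """A region area in mm² with the magnification factor applied."""

    area_mm2: float
    factor: float
    pixel_count: int


def corrected_area(
    mask: RegionMask,
    mm_per_pixel: Optional[float] = None,
    axial_length_mm: Optional[float] = None,
    reference_al_mm: float = REFERENCE_AXIAL_LENGTH_MM,
) -> AreaMeasure:
    """Pixel-count area with optional axial-length magnification correction.

    The lateral scale of a fundus raster varies with the eye's axial length;
    the correction applied here is the squared ratio of the measured axial
    length to the device reference.  Exact Littmann-Bennett coefficients can
    be substituted by adjusting ``reference_al_mm``.
    """
    scale = mm_per_pixel if mm_per_pixel is not None else mask.mm_per_pixel
    if not scale > 0:
        raise ValueError("mm_per_pixel must be positive")
    if axial_length_mm is None:
        axial_length_mm = mask.axial_length_mm
    factor = 1.0
    if axial_length_mm is not None:
        if not (axial_length_mm > 0 and reference_al_mm > 0):
            raise ValueError("axial lengths must be positive")
        factor = (axial_length_mm / reference_al_mm) ** 2
    count = mask.pixel_count
    return AreaMeasure(area_mm2=count * scale * scale * factor,
                       factor=factor, pixel_count=count)


def cv_between(areas: Sequence[float]) -> float:
    """Per-subject coefficient of variation across methods, in percent.

    100 x sample SD / mean of one subject's areas measured by >= 2 methods.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        raise ValueError("CV requires at least two method areas")
    mean = areas.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean area")
    return 100.0 * areas.std(ddof=1) / mean


def mean_ci(values: Sequence[float], confidence: float = 0.95) -> Tuple[float, float, float]:
    """Mean with a t-based confidence interval (mean, lower, upper)."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if values.size < 2:
        return m, m, m
    sem = values.std(ddof=1) / np.sqrt(values.size)
    half = stats.t.ppf(0.5 + confidence / 2.0, values.size - 1) * sem
    return m, m - half, m + half


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, raw * m)."""
    return min(1.0, p * m)


def paired_wilcoxon(x, y) -> Tuple[float, float]:
    """Wilcoxon signed-rank test robust to the all-zero-difference case."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(x, y)
    return float(stat), float(p)


def friedman_with_posthoc(
    table: pd.DataFrame,
) -> Dict:
    """Friedman test across columns (blocks = rows) plus pairwise post-hoc.

    Post-hoc: paired Wilcoxon signed-rank for every column pair, Bonferroni
    adjusted over the number of pairs.  Returns the test statistic, raw p,
    and a post-hoc table with raw and adjusted p-values.
    """
    if table.shape[0] < 3:
        raise ValueError("Friedman test needs >= 3 complete blocks")
    if table.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 groups")
    if table.isna().any().any():
        raise ValueError("incomplete blocks: missing values in the table")
    cols = [table[c].to_numpy(dtype=float) for c in table.columns]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        statistic, pvalue = 0.0, 1.0  # identical groups: nothing to detect
    else:
        statistic, pvalue = stats.friedmanchisquare(*cols)
    pairs = list(itertools.combinations(table.columns, 2))
    rows = []
    for a, b in pairs:
        w_stat, raw = paired_wilcoxon(table[a], table[b])
        rows.append({"group_a": a, "group_b": b, "statistic": w_stat,
                     "p_raw": raw, "p_adj": bonferroni(raw, len(pairs))})
    return {
        "statistic": float(statistic),
        "p": float(pvalue),
        "posthoc": pd.DataFrame(rows),
    }


@dataclass
class EvalRecord:
    """Agreement between two methods' masks on one eye."""

    eye_id: str
    method_a: str
    method_b: str
    area_a_mm2: float
    area_b_mm2: float
    jaccard: float
    dsc: float
    fn_pct: float
    fp_pct: float
    cv_pct: float


def reconcile_masks(a: RegionMask, b: RegionMask) -> Tuple[RegionMask, RegionMask]:
    """Bring two masks onto a common grid (nearest-neighbour, larger -> smaller)."""
    from .annotation_batch import resize_nearest

    if a.shape == b.shape:
        return a, b
    if a.shape[0] != a.shape[1] or b.shape[0] != b.shape[1]:
        raise ImagingError("size reconciliation supports square masks only")
    small = min(a.shape[0], b.shape[0])
    def shrink(m: RegionMask) -> RegionMask:
        if m.shape[0] == small:
            return m
        scale = m.shape[0] / small
        return RegionMask(resize_nearest(m.pixels, small) ,
                          mm_per_pixel=m.mm_per_pixel * scale,
                          eye_id=m.eye_id, axial_length_mm=m.axial_length_mm)
    return shrink(a), shrink(b)


def evaluate_pair(
    eye_id: str,
    method_a: str,
    mask_a: RegionMask,
    method_b: str,
    mask_b: RegionMask,
    axial_length_mm: Optional[float] = None,
    reference_al_mm: float = REFERENCE_AXIAL_LENGTH_MM,
) -> EvalRecord:
    """Full per-eye agreement record for one method pair."""
    a, b = reconcile_masks(mask_a, mask_b)
    j = jaccard(a, b)
    d = dsc(a, b)
    fn, fp = fn_fp(a, b)
    area_a = corrected_area(a, axial_length_mm=axial_length_mm,
                            reference_al_mm=reference_al_mm).area_mm2
    area_b = corrected_area(b, axial_length_mm=axial_length_mm,
                            reference_al_mm=reference_al_mm).area_mm2
    return EvalRecord(
        eye_id=eye_id, method_a=method_a, method_b=method_b,
        area_a_mm2=area_a, area_b_mm2=area_b,
        jaccard=j, dsc=d, fn_pct=fn, fp_pct=fp,
        cv_pct=cv_between([area_a, area_b]),
    )


@dataclass
class ComparisonReport:
    """Everything the comparison battery computes, table-shaped.

    records: one row per eye per method pair (Jaccard, DSC, FN%, FP%, areas, CV).
    pair_summary: per-pair means with 95% CIs.
    area_table: per-method corrected areas (eyes x methods).
    tests: Friedman + post-hoc results for areas, CV, Jaccard and DSC, the
    FN-vs-FP paired Wilcoxon per pair, Spearman area correlations, and
    Shapiro-Wilk normality checks (narrative gating only).
    """

    records: pd.DataFrame
    pair_summary: pd.DataFrame
    area_table: pd.DataFrame
    tests: Dict


def compare_methods(
    masks_by_method: Mapping[str, Mapping[str, RegionMask]],
    axial_lengths: Optional[Mapping[str, float]] = None,
    reference_al_mm: float = REFERENCE_AXIAL_LENGTH_MM,
) -> ComparisonReport:
    """Run the full agreement battery over >= 3 methods on common eyes.

    ``masks_by_method[method][eye_id]`` must form complete blocks: every
    method segmented on every eye, >= 3 eyes.
    """
    methods = list(masks_by_method)
    if len(methods) < 3:
        raise ValueError("comparison battery needs >= 3 methods")
    eye_sets = [set(masks_by_method[m]) for m in methods]
    eyes = sorted(eye_sets[0])
    if any(s != eye_sets[0] for s in eye_sets[1:]):
        raise ValueError("incomplete blocks: methods disagree on the eye set")
    if len(eyes) < 3:
        raise ValueError("comparison battery needs >= 3 eyes (blocks)")
    axial_lengths = axial_lengths or {}

    records = []
    for eye in eyes:
        for m_a, m_b in itertools.combinations(methods, 2):
            records.append(evaluate_pair(
                eye, m_a, masks_by_method[m_a][eye],
                m_b, masks_by_method[m_b][eye],
                axial_length_mm=axial_lengths.get(eye),
                reference_al_mm=reference_al_mm))
    rec = pd.DataFrame([r.__dict__ for r in records])
    rec["pair"] = rec["method_a"] + " vs " + rec["method_b"]

    area_table = pd.DataFrame(
        {m: [corrected_area(masks_by_method[m][e],
                            axial_length_mm=axial_lengths.get(e),
                            reference_al_mm=reference_al_mm).area_mm2
             for e in eyes] for m in methods},
        index=eyes)

    summary_rows = []
    for pair, grp in rec.groupby("pair", sort=False):
        row = {"pair": pair, "n": len(grp)}
        for col in ("jaccard", "dsc", "cv_pct", "fn_pct", "fp_pct"):
            m, lo, hi = mean_ci(grp[col])
            row[f"{col}_mean"], row[f"{col}_lo"], row[f"{col}_hi"] = m, lo, hi
        summary_rows.append(row)
    pair_summary = pd.DataFrame(summary_rows)

    pairs = rec["pair"].unique().tolist()
    wide = {metric: rec.pivot(index="eye_id", columns="pair", values=metric)[pairs]
            for metric in ("jaccard", "dsc", "cv_pct")}

    tests: Dict = {
        "shapiro": {
            metric: tuple(map(float, stats.shapiro(rec[metric])))
            if rec[metric].nunique() > 1 else (float("nan"), float("nan"))
            for metric in ("jaccard", "dsc", "cv_pct", "fn_pct", "fp_pct")
        },
        "area_friedman": friedman_with_posthoc(area_table),
    }
    for metric, table in wide.items():
        if len(pairs) >= 3:
            tests[f"{metric}_friedman"] = friedman_with_posthoc(table)
    fnfp_rows = []
    for pair, grp in rec.groupby("pair", sort=False):
        stat, p = paired_wilcoxon(grp["fn_pct"], grp["fp_pct"])
        fnfp_rows.append({"pair": pair, "statistic": stat, "p": p})
    tests["fn_vs_fp_wilcoxon"] = pd.DataFrame(fnfp_rows)
    spearman_rows = []
    for m_a, m_b in itertools.combinations(methods, 2):
        if area_table[m_a].nunique() > 1 and area_table[m_b].nunique() > 1:
            rho, p = stats.spearmanr(area_table[m_a], area_table[m_b])
        else:
            rho, p = float("nan"), float("nan")
        spearman_rows.append({"pair": f"{m_a} vs {m_b}", "rho": float(rho),
                              "p": float(p)})
    tests["area_spearman"] = pd.DataFrame(spearman_rows)

    return ComparisonReport(records=rec, pair_summary=pair_summary,
                            area_table=area_table, tests=tests)
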