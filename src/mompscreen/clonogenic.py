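"""Clonogenic-survival quantification: colony area, % survival, two-way ANOVA.

Stained colony area is measured macro-style: the well disk is located (or
given), the image is inverted so stain is bright, and stained pixels are
separated by Otsu's threshold (with a contrast guard and a fixed-threshold
fallback for uniformly blank or fully stained wells).  Survival is the
treated covered area as a percentage of the matched untreated 100%-growth
control.  Genotype x dose comparisons use a fixed-effects two-way ANOVA
with Type II sums of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)


@dataclass
class ColonyParams:
    """Thresholding parameters for colony-area measurement.

    ``well_disk`` is (center_row, center_col, radius); when None the disk
    is auto-fitted from the bright well interior.  ``min_contrast`` is the
    minimum stain contrast (intensity units) for Otsu to be trusted; a
    lower-contrast well is resolved by ``fixed_threshold`` — a pixel
    counts as stained when its raw intensity falls below it (the fixed
    dialect of the classic colony-area macro).
    """

    well_disk: Optional[tuple[float, float, float]] = None
    min_contrast: float = 8000.0
    fixed_threshold: float = 30000.0
    disk_erosion: float = 3.0
    border_tolerance: float = 3000.0


@dataclass
class ColonyMeasurement:
    well_id: str
    covered_area: float  # percent of the analyzed well disk
    threshold: float


@dataclass
class AnovaResult:
    factors: list
    table: pd.DataFrame  # index: factor names + Residual; cols: sum_sq, df, F, PR(>F)

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "PR(>F)"])


def _autofit_well_disk(img: np.ndarray, border_tolerance: float) -> tuple[float, float, float]:
    """Locate the well as the complement of the border-connected plate background.

    Assumes the image includes plate background around the well (as stained
    plate scans do); the background is taken as the border-connected region
    within ``border_tolerance`` of the border's median intensity, which is
    insensitive to how much of the well is stained.
    """
    border = np.concatenate([img[0, :], img[-1, :], img[:, 0], img[:, -1]])
    level = float(np.median(border))
    outside_like = np.abs(img - level) <= border_tolerance
    lab, n = ndi.label(outside_like)
    border_labels = np.unique(np.concatenate(
        [lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    outside = np.isin(lab, border_labels[border_labels > 0])
    well = ~outside
    well = ndi.binary_fill_holes(well)
    area = int(well.sum())
    if area == 0:
        raise ValueError("well disk not found: image is all plate background")
    cy, cx = ndi.center_of_mass(well)
    radius = float(np.sqrt(area / np.pi))
    return float(cy), float(cx), radius


def measure_colony_area(
    image: np.ndarray,
    params: Optional[ColonyParams] = None,
    well_id: str = "",
) -> ColonyMeasurement:
    """Percentage of the well disk covered by stained colonies.

    Only total area is measured, so merged colonies are handled
    naturally.  The threshold is re-derived per image (Otsu on the
    inverted in-disk intensities); wells without enough stain contrast
    (blank, or fully stained) fall back to the fixed absolute threshold.
    """
    params = params or ColonyParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("colony image must be single-channel 2-D")
    if params.well_disk is not None:
        cy, cx, radius = params.well_disk
    else:
        cy, cx, radius = _autofit_well_disk(img, params.border_tolerance)
    radius = radius - params.disk_erosion  # avoid the well rim
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    if not disk.any():
        raise ValueError("well disk not found: fitted disk is empty")
    vals = img[disk]

    lo, hi = np.percentile(vals, [2, 98])
    if hi - lo >= params.min_contrast:
        thr = float(threshold_otsu(vals))
        # midpoint refinement: place the cut halfway between class means so
        # the blurred colony edge is split symmetrically (Otsu's threshold
        # drifts toward the smaller class when coverage is unbalanced)
        low, high = vals[vals < thr], vals[vals >= thr]
        if low.size and high.size:
            thr = float(0.5 * (low.mean() + high.mean()))
    else:
        # uniform well: blank vs fully stained, resolved by the fixed rule
        thr = float(params.fixed_threshold)
    stained = vals < thr
    covered = 100.0 * stained.sum() / vals.size
    return ColonyMeasurement(well_id=well_id, covered_area=float(covered), threshold=thr)


def compute_survival(treated: ColonyMeasurement, control: ColonyMeasurement) -> float:
    """Survival as percent of the 100%-growth (untreated, sorted) control."""
    if control.covered_area <= 0:
        raise ValueError("control covered area is zero; survival undefined")
    pct = 100.0 * treated.covered_area / control.covered_area
    if pct > 100.0:
        log.warning("survival %.1f%% exceeds the growth control", pct)
    return float(pct)


def survival_table(records: pd.DataFrame) -> pd.DataFrame:
    """Attach survival % to a measurement table with per-(genotype, drug) controls.

    ``records`` needs columns genotype, drug, dose_uM, replicate,
    covered_area, is_control.  Control rows (is_control) define the 100%
    growth level per (genotype, replicate); treated rows are normalized
    against the matching control.
    """
    out = records.copy()
    ctrl = (
        records[records.is_control]
        .set_index(["genotype", "replicate"])["covered_area"]
    )
    surv = []
    for row in out.itertuples(index=False):
        if row.is_control:
            surv.append(100.0)
            continue
        base = ctrl.loc[(row.genotype, row.replicate)]
        if base <= 0:
            raise ValueError(
                f"control covered area is zero for genotype={row.genotype} "
                f"replicate={row.replicate}")
        surv.append(100.0 * row.covered_area / base)
    out["survival"] = surv
    return out


def two_way_anova(
    records: pd.DataFrame,
    factors: tuple[str, str] = ("genotype", "dose"),
    response: str = "survival",
    interaction: bool = True,
) -> AnovaResult:
    """Fixed-effects two-way ANOVA (Type II sums of squares).

    The interaction term is included when replication permits (positive
    residual degrees of freedom); otherwise it is dropped with a logged
    note.  Degenerate designs in which all groups share one value return
    F = 0, p = 1 rather than 0/0.
    """
    fa, fb = factors
    for f in factors:
        if records[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    n = len(records)
    la, lb = records[fa].nunique(), records[fb].nunique()
    df_full = la * lb  # parameters of the interaction model
    use_inter = interaction and n > df_full
    if interaction and not use_inter:
        log.warning("no replication for interaction; fitting additive model")
    rhs = f"C({fa}) * C({fb})" if use_inter else f"C({fa}) + C({fb})"
    model = smf.ols(f"{response} ~ {rhs}", data=records).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(model, typ=2)

    # resolve degenerate 0/0 cases (identical response in every design cell)
    y = records[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        for idx in table.index:
            if idx != "Residual":
                table.loc[idx, ["sum_sq", "F", "PR(>F)"]] = [0.0, 0.0, 1.0]
    names = [f"C({fa})", f"C({fb})"] + ([f"C({fa}):C({fb})"] if use_inter else [])
    return AnovaResult(factors=names, table=table)
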