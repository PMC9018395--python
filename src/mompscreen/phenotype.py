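"""Per-cell phenotype classification and per-well summaries.

The assay distinguishes four mutually exclusive cell states from the two
reporter channels: apoptotic cells whose mitochondria have all undergone
outer-membrane permeabilization carry translocated Venus-BAX puncta and
have lost mitochondrial OMI-mCherry (BAX_POSITIVE); non-apoptotic cells
retain punctate mitochondrial OMI and show diffuse cytoplasmic BAX
(INTACT); atypical cells with heterogeneous permeabilization carry
suprathreshold puncta in *both* channels (DOUBLE_POSITIVE); and a small
fraction of non-fluorescent cells cannot be phenotyped (NONDETERMINED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .imaging import (
    REPORTER_CHANNELS,
    CellRegion,
    DetectionParams,
    FieldImage,
    Granule,
    NucleusObject,
)

log = logging.getLogger(__name__)


class PhenotypeLabel(str, Enum):
    BAX_POSITIVE = "BAX_POSITIVE"
    INTACT = "INTACT"
    DOUBLE_POSITIVE = "DOUBLE_POSITIVE"
    NONDETERMINED = "NONDETERMINED"


LABELS = tuple(PhenotypeLabel)


@dataclass
class CellRecord:
    """Per-cell feature vector; the unit of classification."""

    cell_id: int
    well_id: str
    site_index: int
    bax_granule_count: int
    bax_granule_total_intensity: float
    omi_granule_count: int
    omi_granule_total_intensity: float
    total_intensity: dict  # reporter channel -> integrated bg-subtracted intensity
    nucleus_fragmented: bool
    label: Optional[PhenotypeLabel] = None


@dataclass
class WellSummary:
    well_id: str
    n_cells: int
    fractions: dict  # PhenotypeLabel -> fraction
    fragmented_fraction: float
    valid: bool = True


def classify_cell(record: CellRecord, params: DetectionParams) -> PhenotypeLabel:
    """Assign a phenotype from suprathreshold granule counts and cell fluorescence.

    Both channels granule-positive -> DOUBLE_POSITIVE; only BAX ->
    BAX_POSITIVE; only OMI -> INTACT; no granules and both reporter
    channels below the fluorescence floor -> NONDETERMINED; otherwise the
    cell is fluorescent but granule-free (diffuse BAX, released OMI) and
    is conservatively treated as INTACT.
    """
    bax = record.bax_granule_count > 0
    omi = record.omi_granule_count > 0
    if bax and omi:
        return PhenotypeLabel.DOUBLE_POSITIVE
    if bax:
        return PhenotypeLabel.BAX_POSITIVE
    if omi:
        return PhenotypeLabel.INTACT
    floors = {ch: params.channels[ch].fluorescence_floor for ch in REPORTER_CHANNELS}
    if all(record.total_intensity.get(ch, 0.0) < floors[ch] for ch in REPORTER_CHANNELS):
        return PhenotypeLabel.NONDETERMINED
    return PhenotypeLabel.INTACT


def extract_cell_records(
    field: FieldImage,
    nuclei: Sequence[NucleusObject],
    regions: Sequence[CellRegion],
    granules: Sequence[Granule],
    params: DetectionParams,
) -> list[CellRecord]:
    """Join segmentation and granule detections into labelled cell records.

    Total cell fluorescence per reporter channel is the integrated
    background-subtracted intensity over the cell region, with the image
    median as the background estimate.
    """
    by_nucleus = {n.label: n for n in nuclei}
    gran_by_cell: dict[int, dict[str, list[Granule]]] = {}
    for g in granules:
        gran_by_cell.setdefault(g.cell_id, {}).setdefault(g.channel, []).append(g)

    bg = {
        ch: float(np.median(np.asarray(field.channels[ch], dtype=float)))
        for ch in REPORTER_CHANNELS
    }
    records = []
    for reg in regions:
        nuc = by_nucleus[reg.cell_id]
        totals = {}
        for ch in REPORTER_CHANNELS:
            img = np.asarray(field.channels[ch], dtype=float)
            vals = img[reg.coords[:, 0], reg.coords[:, 1]] - bg[ch]
            totals[ch] = float(np.clip(vals, 0, None).sum())
        mine = gran_by_cell.get(reg.cell_id, {})
        bax = mine.get("YFP", [])
        omi = mine.get("TexasRed", [])
        rec = CellRecord(
            cell_id=reg.cell_id,
            well_id=field.well_id,
            site_index=field.site_index,
            bax_granule_count=len(bax),
            bax_granule_total_intensity=float(sum(g.integrated_intensity for g in bax)),
            omi_granule_count=len(omi),
            omi_granule_total_intensity=float(sum(g.integrated_intensity for g in omi)),
            total_intensity=totals,
            nucleus_fragmented=nuc.fragmented,
        )
        rec.label = classify_cell(rec, params)
        records.append(rec)
    return records


def summarize_well(
    records: Iterable[CellRecord],
    well_id: str,
    min_cells: int = 50,
) -> WellSummary:
    """Pool cells across a well's sites into phenotype fractions.

    Fractions are computed over all segmented cells pooled across sites
    (sparse sites are not up-weighted).  Wells with fewer than
    ``min_cells`` analyzed cells are flagged invalid and excluded from
    downstream scoring.
    """
    recs = [r for r in records if r.well_id == well_id]
    n = len(recs)
    if n == 0:
        log.warning("well %s has zero analyzed cells; flagged invalid", well_id)
        return WellSummary(
            well_id=well_id,
            n_cells=0,
            fractions={lab: float("nan") for lab in LABELS},
            fragmented_fraction=float("nan"),
            valid=False,
        )
    counts = {lab: 0 for lab in LABELS}
    frag = 0
    for r in recs:
        counts[r.label] += 1
        frag += int(r.nucleus_fragmented)
    fractions = {lab: counts[lab] / n for lab in LABELS}
    valid = n >= min_cells
    if not valid:
        log.warning("well %s has %d < %d cells; flagged invalid", well_id, n, min_cells)
    return WellSummary(
        well_id=well_id,
        n_cells=n,
        fractions=fractions,
        fragmented_fraction=frag / n,
        valid=valid,
    )


def summarize_wells_frame(cells: "pd.DataFrame", min_cells: int = 50) -> list[WellSummary]:
    """Summarize a per-cell table (columns: well, phenotype, fragmented) by well."""
    summaries = []
    for well, grp in cells.groupby("well", sort=True):
        n = len(grp)
        fractions = {
            lab: float((grp.phenotype == lab.value).sum()) / n for lab in LABELS
        }
        summaries.append(
            WellSummary(
                well_id=str(well), n_cells=n, fractions=fractions,
                fragmented_fraction=float(grp.fragmented.astype(bool).mean()),
                valid=n >= min_cells,
            )
        )
    return summaries
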