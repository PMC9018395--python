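"""Reading and writing of the pipeline's on-disk formats.

Images are single-channel 16-bit TIFFs, one file per (well, site,
channel), named ``<plate>_<well>_s<site>_<channel>.tif``; tables are plain
CSV with fixed column sets mirroring the ground-truth schemas so detected
and true objects can be joined.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .imaging import CHANNELS, FieldImage, Granule
from .phenotype import LABELS, CellRecord, WellSummary
from .screen import GeneScore, HitCall, SecondaryResult
from .synthdata import GroundTruthCell

FILENAME_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})_s(?P<site>\d+)_(?P<channel>\w+)\.tif$")


def field_filename(plate: str, well: str, site: int, channel: str) -> str:
    return f"{plate}_{well}_s{site}_{channel}.tif"


def write_field(field: FieldImage, outdir: Path, plate: str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in CHANNELS:
        path = outdir / field_filename(plate, field.well_id, field.site_index, ch)
        tifffile.imwrite(path, np.asarray(field.channels[ch], dtype=np.uint16))
        paths.append(path)
    return paths


def read_field(directory: Path, plate: str, well: str, site: int,
               pixel_size: float = 0.65) -> FieldImage:
    directory = Path(directory)
    channels = {}
    for ch in CHANNELS:
        path = directory / field_filename(plate, well, site, ch)
        channels[ch] = tifffile.imread(path)
    return FieldImage(channels=channels, well_id=well, site_index=site,
                      pixel_size=pixel_size)


def list_fields(directory: Path) -> pd.DataFrame:
    """Inventory a directory of field TIFFs into (plate, well, site) rows."""
    rows = {}
    for path in sorted(Path(directory).glob("*.tif")):
        m = FILENAME_RE.match(path.name)
        if not m:
            continue
        key = (m["plate"], m["well"], int(m["site"]))
        rows.setdefault(key, set()).add(m["channel"])
    out = [
        dict(plate=p, well=w, site=s)
        for (p, w, s), chans in rows.items()
        if set(CHANNELS) <= chans
    ]
    return pd.DataFrame(out, columns=["plate", "well", "site"])


# ---------------------------------------------------------------------------
# ground truth tables


def truth_cells_frame(truth: Iterable[GroundTruthCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cell_id=c.cell_id, well=c.well_id, site=c.site_index,
                y=c.nucleus_centroid[0], x=c.nucleus_centroid[1],
                fragmented=c.nucleus_fragmented, phenotype=c.true_phenotype.value,
            )
            for c in truth
        ],
        columns=["cell_id", "well", "site", "y", "x", "fragmented", "phenotype"],
    )


def truth_puncta_frame(truth: Iterable[GroundTruthCell]) -> pd.DataFrame:
    rows = []
    for c in truth:
        for ch, plist in c.puncta.items():
            for p in plist:
                rows.append(
                    dict(cell_id=c.cell_id, well=c.well_id, site=c.site_index,
                         channel=ch, y=p.centroid[0], x=p.centroid[1],
                         diameter=p.diameter, amplitude=p.amplitude)
                )
    return pd.DataFrame(
        rows, columns=["cell_id", "well", "site", "channel", "y", "x",
                       "diameter", "amplitude"])


# ---------------------------------------------------------------------------
# detection tables


def detected_cells_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cell_id=r.cell_id, well=r.well_id, site=r.site_index,
                bax_granules=r.bax_granule_count, omi_granules=r.omi_granule_count,
                bax_intensity=r.bax_granule_total_intensity,
                omi_intensity=r.omi_granule_total_intensity,
                yfp_total=r.total_intensity.get("YFP", 0.0),
                texasred_total=r.total_intensity.get("TexasRed", 0.0),
                fragmented=r.nucleus_fragmented,
                phenotype=r.label.value if r.label else "",
            )
            for r in records
        ]
    )


def detected_granules_frame(granules: Iterable[Granule], well: str, site: int) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(well=well, site=site, channel=g.channel, y=g.centroid[0],
                 x=g.centroid[1], equivalent_diameter=g.equivalent_diameter,
                 integrated_intensity=g.integrated_intensity, cell_id=g.cell_id)
            for g in granules
        ],
        columns=["well", "site", "channel", "y", "x", "equivalent_diameter",
                 "integrated_intensity", "cell_id"],
    )


def well_summaries_frame(summaries: Iterable[WellSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                well=s.well_id, n_cells=s.n_cells,
                **{f"frac_{lab.value.lower()}": s.fractions[lab] for lab in LABELS},
                frac_fragmented=s.fragmented_fraction, valid=s.valid,
            )
            for s in summaries
        ]
    )


def well_summaries_from_frame(df: pd.DataFrame) -> list[WellSummary]:
    """Rebuild :class:`WellSummary` objects from a well_summaries.csv table."""
    out = []
    for row in df.itertuples(index=False):
        fractions = {lab: getattr(row, f"frac_{lab.value.lower()}") for lab in LABELS}
        out.append(
            WellSummary(well_id=row.well, n_cells=int(row.n_cells), fractions=fractions,
                        fragmented_fraction=row.frac_fragmented, valid=bool(row.valid))
        )
    return out


def gene_scores_frame(scores: Iterable[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene=s.gene, n_replicates=s.n_replicates, bax_fold=s.bax_fold,
                 bax_fold_sem=s.bax_fold_sem, dp_pct=s.dp_pct, dp_pct_sem=s.dp_pct_sem)
            for s in scores
        ]
    )


def hits_frame(hits: Iterable[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene=h.gene, category=h.category, score=h.score, rank=h.rank,
                 tail_fraction=h.tail_fraction, tie_degenerate=h.tie_degenerate)
            for h in hits
        ],
        columns=["gene", "category", "score", "rank", "tail_fraction", "tie_degenerate"],
    )


def secondary_frame(results: Iterable[SecondaryResult]) -> pd.DataFrame:
    cols = ["gene", "sirna1_hit", "sirna2_hit", "sirna3_hit", "sirna4_hit",
            "n_concordant", "confirmed"]
    return pd.DataFrame(
        [
            dict(
                gene=r.gene,
                **{f"sirna{i + 1}_hit": bool(h) for i, h in enumerate(r.sirna_hits)},
                n_concordant=r.n_concordant, confirmed=r.confirmed,
            )
            for r in results
        ],
        columns=cols,
    )
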