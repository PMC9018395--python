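"""End-to-end orchestration: simulate -> detect -> phenotype -> score -> hits.

One :class:`RunConfig` (a YAML file on disk) drives a full reproducible
run.  All randomness derives from the single run seed by stream
splitting, so re-running an identical config is byte-identical; the run
manifest records the config hash, seed, library versions, per-stage row
counts and a content hash of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .clonogenic import (
    ColonyParams,
    measure_colony_area,
    survival_table,
    two_way_anova,
)
from .imaging import (
    REPORTER_CHANNELS,
    DetectionParams,
    FieldImage,
    assign_cell_regions,
    detect_granules,
    segment_nuclei,
)
from .phenotype import PhenotypeLabel, extract_cell_records, summarize_well
from .screen import (
    CATEGORIES,
    call_primary_hits,
    compute_zprime,
    confirm_secondary,
    score_genes,
    threshold_rule_from_hits,
)
from .synthdata import (
    SimulationConfig,
    field_rng,
    generate_plate_layout,
    render_field,
    sample_field_truth,
    simulate_secondary_scores,
    simulate_well_summaries,
    well_mixture,
)

log = logging.getLogger(__name__)


def analyze_field(field_image: FieldImage, params: DetectionParams):
    """Run the image front end on one field; returns (nuclei, regions, granules, records)."""
    nuclei = segment_nuclei(np.asarray(field_image.channels["DAPI"], dtype=float), params)
    regions = assign_cell_regions(nuclei, field_image.shape, params)
    granules = []
    for ch in REPORTER_CHANNELS:
        granules.extend(detect_granules(field_image.channels[ch], regions, params, ch))
    records = extract_cell_records(field_image, nuclei, regions, granules, params)
    return nuclei, regions, granules, records


@dataclass
class RunConfig:
    """Validated configuration of a full screen run."""

    n_genes: int = 24
    replicates: int = 3
    spiked: dict = field(default_factory=dict)  # gene -> {category: multiplier}
    mode: str = "scores"  # "scores" (imageless) or "images" (full front end)
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    detection: dict = field(default_factory=dict)  # DetectionParams overrides
    tail_fraction: float = 0.10
    min_concordant: int = 3
    secondary_reproducibility: float = 0.9
    min_cells_per_well: int = 50
    save_images: bool = False
    seed: int = 0
    outdir: str = "mompscreen_run"

    def validate(self) -> None:
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError(f"tail_fraction must be in (0, 0.5), got {self.tail_fraction}")
        if self.min_concordant not in (1, 2, 3, 4):
            raise ValueError(f"min_concordant must be in 1..4, got {self.min_concordant}")
        if self.mode not in ("scores", "images"):
            raise ValueError(f"mode must be 'scores' or 'images', got {self.mode!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def canonical(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulation_config(config: RunConfig) -> SimulationConfig:
    return SimulationConfig(**config.simulation, seed=config.seed)


def _image_mode_summaries(config: RunConfig, sim_cfg: SimulationConfig,
                          plate_map: pd.DataFrame, params: DetectionParams,
                          outdir: Path):
    """Render and analyze every scored well field-by-field."""
    summaries = []
    imgdir = outdir / "images"
    scored_roles = ("SAMPLE", "NEG_CONTROL", "POS_CONTROL", "UNTREATED")
    for row in plate_map.itertuples(index=False):
        if row.role not in scored_roles:
            continue
        wid = f"{row.plate_id}/{row.well}"
        mixture = well_mixture(row.role, row.gene, sim_cfg, config.spiked or None)
        records = []
        for site in range(sim_cfg.sites_per_well):
            rng = field_rng(config.seed, row.plate * 10 + row.replicate,
                            row.row, row.column, site)
            truth = sample_field_truth(sim_cfg, rng, well_id=wid, site_index=site,
                                       mixture=mixture)
            render_seed = int(rng.integers(2 ** 31))
            fimg = render_field(truth, sim_cfg, render_seed, well_id=wid, site_index=site)
            if config.save_images:
                mio.write_field(fimg, imgdir, row.plate_id)
            _, _, _, recs = analyze_field(fimg, params)
            records.extend(recs)
        summaries.append(summarize_well(records, wid, min_cells=config.min_cells_per_well))
    return summaries


def run_screen(config: RunConfig, outdir: Optional[Path] = None) -> dict:
    """Execute the full screen pipeline and write all outputs + manifest."""
    config.validate()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = _simulation_config(config)
    params = DetectionParams(**config.detection)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    stage = "layout"
    try:
        plate_map = generate_plate_layout(sim_cfg, genes, replicates=config.replicates)
        plate_map.to_csv(outdir / "plate_map.csv", index=False)

        stage = "simulate+phenotype"
        if config.mode == "scores":
            summaries = simulate_well_summaries(plate_map, sim_cfg, config.seed,
                                                effects=config.spiked or None)
        else:
            summaries = _image_mode_summaries(config, sim_cfg, plate_map, params, outdir)
        mio.well_summaries_frame(summaries).to_csv(outdir / "well_summaries.csv", index=False)

        stage = "qc"
        qc_rows = []
        by_well = {s.well_id: s for s in summaries}
        bp = PhenotypeLabel.BAX_POSITIVE
        for plate_id, grp in plate_map.groupby("plate_id"):
            pos = [by_well[f"{plate_id}/{w}"].fractions[bp]
                   for w in grp[grp.role == "NEG_CONTROL"].well
                   if f"{plate_id}/{w}" in by_well and by_well[f"{plate_id}/{w}"].valid]
            neg = [by_well[f"{plate_id}/{w}"].fractions[bp]
                   for w in grp[grp.role == "UNTREATED"].well
                   if f"{plate_id}/{w}" in by_well and by_well[f"{plate_id}/{w}"].valid]
            if len(pos) >= 2 and len(neg) >= 2:
                qc_rows.append(dict(plate_id=plate_id,
                                    zprime=compute_zprime(pos, neg)))
        pd.DataFrame(qc_rows, columns=["plate_id", "zprime"]).to_csv(
            outdir / "qc.csv", index=False)

        stage = "score"
        scores = score_genes(summaries, plate_map)
        mio.gene_scores_frame(scores).to_csv(outdir / "gene_scores.csv", index=False)

        stage = "call-hits"
        all_hits = []
        hits_by_cat = {}
        for cat in CATEGORIES:
            hits = call_primary_hits(scores, cat, tail_fraction=config.tail_fraction)
            hits_by_cat[cat] = hits
            all_hits.extend(hits)
        mio.hits_frame(all_hits).to_csv(outdir / "primary_hits.csv", index=False)

        stage = "confirm"
        cat3 = hits_by_cat["III"]
        secondary_results = []
        if cat3:
            hit_genes = [h.gene for h in cat3]
            effects = {g: config.spiked.get(g, {}).get("III", 1.0) for g in hit_genes}
            per_sirna = simulate_secondary_scores(
                hit_genes, effects, config.secondary_reproducibility, seed=config.seed)
            rule = threshold_rule_from_hits(cat3, "III")
            secondary_results = confirm_secondary(per_sirna, rule,
                                                  min_concordant=config.min_concordant)
        mio.secondary_frame(secondary_results).to_csv(
            outdir / "secondary_results.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    stage = "manifest"
    outputs = ["plate_map.csv", "well_summaries.csv", "qc.csv", "gene_scores.csv",
               "primary_hits.csv", "secondary_results.csv"]
    manifest = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_plates": int(plate_map.plate.nunique()),
        "n_replicates": int(plate_map.replicate.nunique()),
        "rows": {},
        "files": {},
    }
    for name in outputs:
        path = outdir / name
        try:
            n_rows = int(len(pd.read_csv(path)))
        except pd.errors.EmptyDataError:
            n_rows = 0
        manifest["rows"][name] = n_rows
        manifest["files"][name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# clonogenic arm


def run_clonogenic(design_csv: Path, outdir: Path,
                   params: Optional[ColonyParams] = None,
                   interaction: bool = True) -> dict:
    """Measure colony areas for a survival design and run the ANOVA.

    ``design_csv`` columns: genotype, drug, dose_uM, replicate, well,
    image_path (relative to the CSV), is_control.
    """
    design_csv = Path(design_csv)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = pd.read_csv(design_csv)
    params = params or ColonyParams()

    import tifffile

    covered = []
    for row in design.itertuples(index=False):
        img_path = design_csv.parent / row.image_path
        img = tifffile.imread(img_path)
        m = measure_colony_area(img, params, well_id=row.well)
        covered.append(m.covered_area)
    design = design.assign(covered_area=covered)
    design.to_csv(outdir / "colony_areas.csv", index=False)

    surv = survival_table(design)
    surv.to_csv(outdir / "survival.csv", index=False)

    treated = surv[~surv.is_control].rename(columns={"dose_uM": "dose"})
    result = two_way_anova(treated, factors=("genotype", "dose"),
                           interaction=interaction)
    with open(outdir / "anova.txt", "w") as fh:
        fh.write(result.table.to_string())
        fh.write("\n")
    return {"n_wells": len(design), "anova": result}
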