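"""Seeded generators of synthetic screen data with exact ground truth.

Emulates the statistical structure the analysis assumes, at three levels:

* **Field images** — three-channel 16-bit rasters (nuclear stain, Venus-BAX
  in YFP, OMI-mCherry in Texas Red) with per-cell ground truth.  Nuclei are
  smooth blobs (apoptotic ones rendered as 2–4 sub-normal fragments),
  cytoplasm is a soft disk of diffuse fluorescence, and puncta are 2-D
  Gaussians whose FWHM is the true diameter.  Apoptotic cells carry YFP
  puncta only; intact cells carry Texas Red puncta only; double-positive
  cells carry non-colocalized puncta in both channels; nondetermined cells
  are sub-floor in both reporters.
* **Score tables** — imageless per-gene, per-replicate assay scores with
  known spiked effects, for testing screen statistics at full scale.
* **Colony wells** — crystal-violet-like single-channel images of merged
  colony blobs with a known covered-area fraction.

All generators are deterministic given (config, seed); independent RNG
streams are derived per (plate, well, site) by seed-sequence splitting so
subsets regenerate identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import CHANNELS, REPORTER_CHANNELS, UINT16_MAX, FieldImage
from .phenotype import LABELS, PhenotypeLabel, WellSummary

log = logging.getLogger(__name__)

ROLES = ("SAMPLE", "NEG_CONTROL", "POS_CONTROL", "TOX_MARKER", "UNTREATED", "EMPTY_EDGE")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PunctaSpec:
    """Per-channel puncta statistics for positive cells."""

    count_mean: float = 10.0
    count_min: int = 1
    diameter_range: tuple[float, float] = (3.0, 7.0)
    amplitude: float = 3000.0
    amplitude_cv: float = 0.25

    def __post_init__(self) -> None:
        if not self.diameter_range[0] < self.diameter_range[1]:
            raise ValueError("diameter range min must be < max")


def _default_mixture() -> dict[str, float]:
    # etoposide + caspase-inhibitor treated population: mostly fully
    # apoptotic or intact, few heterogeneous, small nonfluorescent fraction
    return {
        "BAX_POSITIVE": 0.50,
        "INTACT": 0.40,
        "DOUBLE_POSITIVE": 0.03,
        "NONDETERMINED": 0.07,
    }


def _default_puncta() -> dict[str, PunctaSpec]:
    return {
        "YFP": PunctaSpec(count_mean=10.0),
        "TexasRed": PunctaSpec(count_mean=12.0),
    }


def _default_diffuse() -> dict[str, dict[str, float]]:
    # diffuse cytoplasmic amplitude above background, per phenotype/channel
    return {
        "BAX_POSITIVE": {"YFP": 80.0, "TexasRed": 15.0},
        "INTACT": {"YFP": 100.0, "TexasRed": 40.0},
        "DOUBLE_POSITIVE": {"YFP": 80.0, "TexasRed": 30.0},
        "NONDETERMINED": {"YFP": 0.0, "TexasRed": 0.0},
    }


@dataclass
class SimulationConfig:
    """Geometry, plate layout, population mixture and optics of the simulation."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.65  # micrometres per pixel (20x widefield)
    plate_format: tuple[int, int] = (16, 24)  # 384-well
    excluded_edge: int = 2  # rows/columns left untransfected at each edge
    sites_per_well: int = 16
    cells_per_field: float = 50.0  # Poisson mean
    phenotype_mixture: dict = field(default_factory=_default_mixture)
    puncta: dict = field(default_factory=_default_puncta)
    diffuse: dict = field(default_factory=_default_diffuse)
    background_level: float = 200.0
    noise_sigma: float = 30.0
    shot_noise: bool = True
    nucleus_radius: float = 9.0
    nucleus_axis_ratio_max: float = 1.4
    dapi_amplitude: float = 3000.0
    fragmented_fraction_apoptotic: float = 0.5
    min_cell_separation: float = 46.0
    cell_radius: float = 20.0
    puncta_radial_range: tuple[float, float] = (6.0, 18.0)
    noncoloc_min_distance: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.phenotype_mixture
        vals = np.array([p[lab.value] if not isinstance(lab, str) else p[lab]
                         for lab in (l.value for l in LABELS)], dtype=float)
        if (vals < 0).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("phenotype_mixture must be non-negative and sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.excluded_edge < 0:
            raise ValueError("excluded_edge must be >= 0")


def field_rng(seed: int, plate: int = 0, well_row: int = 0, well_col: int = 0,
              site: int = 0) -> np.random.Generator:
    """Independent RNG stream for one (plate, well, site), split from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(plate, well_row, well_col, site))
    )


# ---------------------------------------------------------------------------
# plate layout


def well_name(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def generate_plate_layout(
    config: SimulationConfig,
    gene_list: Sequence[str],
    replicates: int = 3,
    controls_per_plate: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Arrange genes and control wells on replicate plates.

    Edge wells in the excluded band carry role EMPTY_EDGE (they receive
    cells and medium but no transfection).  Within the usable area the
    first wells (row-major) host the control set — nontargeting negative
    controls, a BAX-pool positive control, toxicity/transfection markers
    and untreated wells — and the genes fill the remainder, one well per
    gene per replicate plate.
    """
    if controls_per_plate is None:
        controls_per_plate = {
            "NEG_CONTROL": 2, "POS_CONTROL": 2, "TOX_MARKER": 2, "UNTREATED": 2,
        }
    n_rows, n_cols = config.plate_format
    e = config.excluded_edge
    usable = [
        (r, c)
        for r in range(e, n_rows - e)
        for c in range(e, n_cols - e)
    ]
    n_controls = sum(controls_per_plate.values())
    capacity = len(usable) - n_controls
    if capacity < 0:
        raise ValueError(
            f"plate capacity exceeded: {n_controls} control wells required, "
            f"{len(usable)} usable wells available"
        )
    genes = list(gene_list)
    if genes and capacity == 0:
        raise ValueError(
            f"plate capacity exceeded: 0 sample wells available for {len(genes)} genes"
        )
    n_plates = max(1, math.ceil(len(genes) / capacity)) if capacity else 1

    control_roles: list[str] = []
    for role in ("NEG_CONTROL", "POS_CONTROL", "TOX_MARKER", "UNTREATED"):
        control_roles += [role] * controls_per_plate.get(role, 0)

    rows = []
    gene_iter = iter(genes)
    for plate in range(1, n_plates + 1):
        plate_genes = [g for _, g in zip(range(capacity), gene_iter)]
        for rep in range(1, replicates + 1):
            plate_id = f"P{plate:02d}R{rep}"
            gi = iter(plate_genes)
            for r in range(n_rows):
                for c in range(n_cols):
                    if (r, c) not in usable:
                        role, gene = "EMPTY_EDGE", ""
                    else:
                        idx = usable.index((r, c))
                        if idx < n_controls:
                            role, gene = control_roles[idx], ""
                        else:
                            gene = next(gi, "")
                            role = "SAMPLE" if gene else "EMPTY_EDGE"
                            if not gene:
                                continue  # unused usable well: leave out
                    treatment = "NONE" if role in ("UNTREATED", "EMPTY_EDGE") else "ETOPOSIDE_QVD"
                    rows.append(
                        dict(
                            plate=plate,
                            replicate=rep,
                            plate_id=plate_id,
                            well=well_name(r, c),
                            row=r,
                            column=c,
                            role=role,
                            gene=gene,
                            sirna_id=f"{gene}_pool" if gene else "",
                            treatment=treatment,
                        )
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground-truth cells and field rendering


@dataclass
class Punctum:
    centroid: tuple[float, float]
    diameter: float
    amplitude: float


@dataclass
class GroundTruthCell:
    cell_id: int
    well_id: str
    site_index: int
    nucleus_centroid: tuple[float, float]
    nucleus_fragmented: bool
    true_phenotype: PhenotypeLabel
    puncta: dict  # channel -> list[Punctum]
    diffuse: dict  # channel -> amplitude
    nucleus_fragments: list = field(default_factory=list)  # (cy, cx, ry, rx, angle)


def _sample_positions(rng: np.random.Generator, n: int, shape: tuple[int, int],
                      margin: float, min_sep: float) -> list[tuple[float, float]]:
    pos: list[tuple[float, float]] = []
    h, w = shape
    attempts = 0
    while len(pos) < n and attempts < 400 * max(n, 1):
        attempts += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep ** 2 for py, px in pos):
            pos.append((y, x))
    if len(pos) < n:
        log.warning("placed only %d of %d cells (field too crowded)", len(pos), n)
    return pos


def _sample_puncta(rng: np.random.Generator, spec: PunctaSpec, center: tuple[float, float],
                   radial: tuple[float, float], existing: list[Punctum],
                   cross: list[Punctum], cross_min: float,
                   n_override: Optional[int] = None) -> list[Punctum]:
    n = n_override if n_override is not None else max(spec.count_min, int(rng.poisson(spec.count_mean)))
    # batch-draw candidates, accept greedily under the separation rules
    n_cand = 120 * max(n, 1)
    r = rng.uniform(*radial, size=n_cand)
    th = rng.uniform(0, 2 * np.pi, size=n_cand)
    ys = center[0] + r * np.sin(th)
    xs = center[1] + r * np.cos(th)
    ds = rng.uniform(*spec.diameter_range, size=n_cand)
    amps = spec.amplitude * np.maximum(
        0.3, 1.0 + spec.amplitude_cv * rng.standard_normal(size=n_cand))

    acc_y = np.array([p.centroid[0] for p in existing])
    acc_x = np.array([p.centroid[1] for p in existing])
    acc_d = np.array([p.diameter for p in existing])
    cross_y = np.array([p.centroid[0] for p in cross])
    cross_x = np.array([p.centroid[1] for p in cross])
    out: list[Punctum] = []
    for i in range(n_cand):
        if len(out) >= n:
            break
        if acc_y.size and np.any(
            np.hypot(ys[i] - acc_y, xs[i] - acc_x) < (ds[i] + acc_d) / 2 + 3
        ):
            continue
        if cross_y.size and np.any(
            np.hypot(ys[i] - cross_y, xs[i] - cross_x) < cross_min
        ):
            continue
        out.append(Punctum(centroid=(float(ys[i]), float(xs[i])),
                           diameter=float(ds[i]), amplitude=float(amps[i])))
        acc_y = np.append(acc_y, ys[i])
        acc_x = np.append(acc_x, xs[i])
        acc_d = np.append(acc_d, ds[i])
    if len(out) < n:
        log.debug("placed %d of %d puncta", len(out), n)
    return out


def sample_field_truth(
    config: SimulationConfig,
    rng: np.random.Generator,
    well_id: str = "A01",
    site_index: int = 0,
    n_cells: Optional[int] = None,
    mixture: Optional[Mapping[str, float]] = None,
    cell_id_start: int = 1,
) -> list[GroundTruthCell]:
    """Draw ground-truth cells for one field from the phenotype mixture."""
    mix = dict(mixture or config.phenotype_mixture)
    probs = np.array([mix[lab.value] for lab in LABELS], dtype=float)
    probs = probs / probs.sum()
    n = n_cells if n_cells is not None else int(rng.poisson(config.cells_per_field))
    margin = config.puncta_radial_range[1] + 10.0
    centers = _sample_positions(rng, n, config.image_shape, margin, config.min_cell_separation)

    cells: list[GroundTruthCell] = []
    for i, center in enumerate(centers):
        lab = LABELS[rng.choice(len(LABELS), p=probs)]
        fragmented = bool(
            lab is PhenotypeLabel.BAX_POSITIVE
            and rng.random() < config.fragmented_fraction_apoptotic
        )
        fragments = []
        if fragmented:
            # fragments stay within the segmentation grouping radius (15 px),
            # separated enough not to fuse after smoothing, and each well
            # below the normal-nucleus minimum area
            k = int(rng.integers(2, 5))
            # adjacent fragments stay under the 15 px grouping radius:
            # pair distance is 2*ring*sin(pi/k)
            ring = {2: rng.uniform(5.5, 7.0), 3: rng.uniform(7.0, 8.0),
                    4: rng.uniform(7.0, 9.0)}[k]
            theta0 = rng.uniform(0, 2 * np.pi)
            for j in range(k):
                th = theta0 + 2 * np.pi * j / k
                fy = center[0] + ring * np.sin(th)
                fx = center[1] + ring * np.cos(th)
                rad = rng.uniform(2.4, 2.8)
                fragments.append((fy, fx, rad, rad, 0.0))
        else:
            ratio = rng.uniform(1.0, config.nucleus_axis_ratio_max)
            ry = config.nucleus_radius * np.sqrt(ratio)
            rx = config.nucleus_radius / np.sqrt(ratio)
            fragments.append((center[0], center[1], float(ry), float(rx),
                              float(rng.uniform(0, np.pi))))

        puncta: dict[str, list[Punctum]] = {ch: [] for ch in REPORTER_CHANNELS}
        if lab is PhenotypeLabel.BAX_POSITIVE:
            puncta["YFP"] = _sample_puncta(
                rng, config.puncta["YFP"], center, config.puncta_radial_range, [], [], 0.0)
        elif lab is PhenotypeLabel.INTACT:
            puncta["TexasRed"] = _sample_puncta(
                rng, config.puncta["TexasRed"], center, config.puncta_radial_range, [], [], 0.0)
        elif lab is PhenotypeLabel.DOUBLE_POSITIVE:
            puncta["YFP"] = _sample_puncta(
                rng, config.puncta["YFP"], center, config.puncta_radial_range, [], [], 0.0)
            puncta["TexasRed"] = _sample_puncta(
                rng, config.puncta["TexasRed"], center, config.puncta_radial_range,
                [], puncta["YFP"], config.noncoloc_min_distance)
            # heterogeneous permeabilization needs at least one punctum per channel
            if not puncta["YFP"] or not puncta["TexasRed"]:
                lab = PhenotypeLabel.NONDETERMINED if not (puncta["YFP"] or puncta["TexasRed"]) \
                    else (PhenotypeLabel.BAX_POSITIVE if puncta["YFP"] else PhenotypeLabel.INTACT)

        cells.append(
            GroundTruthCell(
                cell_id=cell_id_start + i,
                well_id=well_id,
                site_index=site_index,
                nucleus_centroid=center,
                nucleus_fragmented=fragmented,
                true_phenotype=lab,
                puncta=puncta,
                diffuse=dict(config.diffuse[lab.value]),
                nucleus_fragments=fragments,
            )
        )
    return cells


def _stamp_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    win = int(np.ceil(3.5 * sigma))
    rlo, rhi = max(0, int(cy) - win), min(h, int(cy) + win + 1)
    clo, chi = max(0, int(cx) - win), min(w, int(cx) + win + 1)
    if rlo >= rhi or clo >= chi:
        return
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2)
    )


def _stamp_soft_ellipse(img: np.ndarray, cy: float, cx: float, ry: float, rx: float,
                        angle: float, amp: float, edge: float = 1.5) -> None:
    h, w = img.shape
    win = int(np.ceil(max(ry, rx) + 3 * edge))
    rlo, rhi = max(0, int(cy) - win), min(h, int(cy) + win + 1)
    clo, chi = max(0, int(cx) - win), min(w, int(cx) + win + 1)
    if rlo >= rhi or clo >= chi:
        return
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    # signed radial excess in units of the local radius
    rad = np.sqrt((u / ry) ** 2 + (v / rx) ** 2)
    soft = np.clip((1.0 - rad) * min(ry, rx) / edge + 0.5, 0.0, 1.0)
    img[rlo:rhi, clo:chi] += amp * soft


def render_field(
    truth: Sequence[GroundTruthCell],
    config: SimulationConfig,
    seed: int,
    well_id: Optional[str] = None,
    site_index: Optional[int] = None,
) -> FieldImage:
    """Render three 16-bit channel rasters from ground-truth cells.

    Deterministic given (truth, config, seed).  Intensities exceeding the
    16-bit range are clipped with a logged warning.
    """
    h, w = config.image_shape
    for cell in truth:
        cy, cx = cell.nucleus_centroid
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"cell {cell.cell_id} centroid outside image")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(101,)))
    planes = {ch: np.zeros((h, w), dtype=float) for ch in CHANNELS}

    for cell in truth:
        cy, cx = cell.nucleus_centroid
        for fy, fx, ry, rx, ang in cell.nucleus_fragments:
            _stamp_soft_ellipse(planes["DAPI"], fy, fx, ry, rx, ang, config.dapi_amplitude)
        for ch in REPORTER_CHANNELS:
            amp = cell.diffuse.get(ch, 0.0)
            if amp > 0:
                _stamp_soft_ellipse(planes[ch], cy, cx, config.cell_radius + 2,
                                    config.cell_radius + 2, 0.0, amp, edge=3.0)
            for p in cell.puncta.get(ch, []):
                sigma = p.diameter / 2.3548  # FWHM -> sigma
                _stamp_gaussian(planes[ch], p.centroid[0], p.centroid[1], sigma, p.amplitude)

    out = {}
    clipped = False
    for ch in CHANNELS:
        img = planes[ch] + config.background_level
        if config.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        if (img > UINT16_MAX).any():
            clipped = True
        out[ch] = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
    if clipped:
        log.warning("rendered intensities exceeded 16-bit range; clipped")

    wid = well_id if well_id is not None else (truth[0].well_id if truth else "A01")
    site = site_index if site_index is not None else (truth[0].site_index if truth else 0)
    return FieldImage(channels=out, well_id=wid, site_index=site,
                      pixel_size=config.pixel_size)


def simulate_field(
    config: SimulationConfig,
    seed: int,
    well_id: str = "A01",
    site_index: int = 0,
    n_cells: Optional[int] = None,
    mixture: Optional[Mapping[str, float]] = None,
) -> tuple[FieldImage, list[GroundTruthCell]]:
    """Convenience: sample ground truth and render it with one seed."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(7,)))
    truth = sample_field_truth(config, rng, well_id=well_id, site_index=site_index,
                               n_cells=n_cells, mixture=mixture)
    fimg = render_field(truth, config, seed, well_id=well_id, site_index=site_index)
    return fimg, truth


# ---------------------------------------------------------------------------
# role/gene mixtures and imageless well summaries


ROLE_MIXTURES = {
    # untreated cells: intact, minimal apoptosis
    "UNTREATED": {"BAX_POSITIVE": 0.02, "INTACT": 0.90,
                  "DOUBLE_POSITIVE": 0.005, "NONDETERMINED": 0.075},
    # BAX-pool positive control: puncta formation suppressed, reporter dimmed
    "POS_CONTROL": {"BAX_POSITIVE": 0.03, "INTACT": 0.77,
                    "DOUBLE_POSITIVE": 0.005, "NONDETERMINED": 0.195},
}


def apply_effects(mixture: Mapping[str, float],
                  effects: Optional[Mapping[str, float]]) -> dict[str, float]:
    """Multiply selected class probabilities, rebalancing the others.

    ``effects`` maps screen categories to multipliers: 'I'/'II' act on the
    BAX_POSITIVE fraction, 'III' on the DOUBLE_POSITIVE fraction.  The
    target class is scaled exactly (capped at 0.9) and the remaining mass
    is redistributed proportionally, so fold-changes of the target class
    realize the requested multiplier.
    """
    mix = dict(mixture)
    if not effects:
        return mix
    targets = {"I": "BAX_POSITIVE", "II": "BAX_POSITIVE", "III": "DOUBLE_POSITIVE"}
    for cat, mult in effects.items():
        cls = targets[cat]
        p_old = mix[cls]
        p_new = min(p_old * mult, 0.9)
        rest = 1.0 - p_old
        scale = (1.0 - p_new) / rest if rest > 0 else 0.0
        for k in mix:
            mix[k] = mix[k] * scale if k != cls else p_new
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def well_mixture(role: str, gene: str, config: SimulationConfig,
                 effects: Optional[Mapping[str, Mapping[str, float]]] = None) -> dict[str, float]:
    if role in ROLE_MIXTURES:
        return dict(ROLE_MIXTURES[role])
    base = dict(config.phenotype_mixture)
    if role == "SAMPLE" and effects and gene in effects:
        return apply_effects(base, effects[gene])
    return base


def simulate_well_summaries(
    plate_map: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
    effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    cells_per_well: Optional[float] = None,
) -> list[WellSummary]:
    """Draw per-well phenotype counts multinomially (no images).

    Each scored well receives ``n ~ Poisson(sites_per_well x
    cells_per_field)`` cells whose labels follow the role/gene mixture, so
    well-to-well variation is exactly the counting noise the image-level
    pipeline would see at the same cell numbers.
    """
    mean_cells = cells_per_well if cells_per_well is not None \
        else config.sites_per_well * config.cells_per_field
    summaries = []
    for row in plate_map.itertuples(index=False):
        if row.role in ("EMPTY_EDGE", "TOX_MARKER"):
            continue
        wid = f"{row.plate_id}/{row.well}"  # plate-qualified: wells recur across plates
        rng = field_rng(seed, row.plate * 10 + row.replicate, row.row, row.column)
        mix = well_mixture(row.role, row.gene, config, effects)
        probs = np.array([mix[lab.value] for lab in LABELS])
        n = int(rng.poisson(mean_cells))
        if n == 0:
            summaries.append(WellSummary(wid, 0,
                                         {lab: float("nan") for lab in LABELS},
                                         float("nan"), valid=False))
            continue
        counts = rng.multinomial(n, probs / probs.sum())
        fractions = {lab: counts[i] / n for i, lab in enumerate(LABELS)}
        n_bp = counts[list(LABELS).index(PhenotypeLabel.BAX_POSITIVE)]
        frag = rng.binomial(n_bp, config.fragmented_fraction_apoptotic) / n if n else 0.0
        summaries.append(WellSummary(wid, int(n), fractions, float(frag)))
    return summaries


# ---------------------------------------------------------------------------
# imageless score tables


def simulate_screen_scores(
    n_genes: int,
    spiked_effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    dp_baseline_pct: float = 2.0,
    cv: Optional[float] = None,
) -> pd.DataFrame:
    """Per-gene, per-replicate assay scores around control baselines.

    Category I/II share one statistic (fold-change of the BAX-positive
    fraction vs nontargeting controls, baseline 1.0); category III is the
    double-positive percentage (baseline ``dp_baseline_pct``).  Spiked
    effects multiply the relevant baseline.  Noise is additive Gaussian
    with ``noise_sd`` (score units) or, when ``cv`` is given,
    multiplicative with that coefficient of variation.  The spike table is
    attached as ``df.attrs['spikes']``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spiked_effects = dict(spiked_effects or {})
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(55,)))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    named = {}
    for g, eff in spiked_effects.items():
        if g not in genes:
            raise KeyError(f"spiked gene {g!r} not in generated gene set G00001..G{n_genes:05d}")
        named[g] = dict(eff)

    rows = []
    for g in genes:
        eff = named.get(g, {})
        fold_mult = eff.get("I", eff.get("II", 1.0))
        dp_mult = eff.get("III", 1.0)
        for rep in range(1, replicates + 1):
            base_fold = 1.0 * fold_mult
            base_dp = dp_baseline_pct * dp_mult
            if cv is not None:
                fold = base_fold * (1.0 + cv * rng.standard_normal())
                dp = base_dp * (1.0 + cv * rng.standard_normal())
            else:
                fold = base_fold + noise_sd * rng.standard_normal()
                dp = base_dp + noise_sd * rng.standard_normal()
            rows.append(dict(gene=g, replicate=rep,
                             bax_fold=max(fold, 0.0), dp_pct=max(dp, 0.0)))
    df = pd.DataFrame(rows)
    df.attrs["spikes"] = named
    df.attrs["dp_baseline_pct"] = dp_baseline_pct
    return df


def simulate_secondary_scores(
    genes: Sequence[str],
    effect,
    reproducibility: float,
    seed: int = 0,
    dp_baseline_pct: float = 2.0,
    cv: float = 0.2,
) -> dict[str, list[float]]:
    """Per-siRNA (4 per gene) category-III scores for a secondary screen.

    Each individual siRNA reproduces the pooled effect with probability
    ``reproducibility``; otherwise it scores at baseline.  ``effect`` is a
    single multiplier or a mapping gene -> multiplier.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(56,)))
    out = {}
    for g in genes:
        mult = effect.get(g, 1.0) if isinstance(effect, Mapping) else float(effect)
        scores = []
        for _ in range(4):
            base = dp_baseline_pct * (mult if rng.random() < reproducibility else 1.0)
            scores.append(max(base * (1.0 + cv * rng.standard_normal()), 0.0))
        out[g] = scores
    return out


# ---------------------------------------------------------------------------
# colony wells


@dataclass
class ColonyRenderConfig:
    image_size: int = 800
    well_margin: int = 20
    background_level: float = 45000.0  # unstained well interior (light)
    stain_level: float = 15000.0  # crystal-violet stained colony (dark)
    outside_level: float = 5000.0  # plate outside the well
    noise_sigma: float = 300.0
    colony_radius_mean: float = 18.0
    colony_radius_cv: float = 0.4
    smooth_sigma: float = 1.0


@dataclass
class ColonyImage:
    image: np.ndarray
    mask: np.ndarray  # ground-truth stained mask (inside well)
    well_center: tuple[float, float]
    well_radius: float
    requested_fraction: float
    realized_fraction: float
    n_colonies: int


def _colony_mask(centers: np.ndarray, radii: np.ndarray, scale: float,
                 shape: tuple[int, int], disk_mask: np.ndarray) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for (cy, cx), r0 in zip(centers, radii):
        r = r0 * scale
        rlo, rhi = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        clo, chi = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        yy, xx = np.mgrid[rlo:rhi, clo:chi]
        mask[rlo:rhi, clo:chi] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    mask &= disk_mask
    return mask


def render_colony_well(
    covered_fraction: float,
    n_colonies: int,
    config: Optional[ColonyRenderConfig] = None,
    seed: int = 0,
) -> ColonyImage:
    """Render a crystal-violet-like well image at a known covered fraction.

    Colony blobs may merge; a global radius scale is bisected until the
    realized covered fraction is within 1 percentage point (in practice
    much closer) of the request.  The realized value is recorded in the
    returned ground truth.
    """
    if not 0.0 <= covered_fraction <= 1.0:
        raise ValueError("covered_fraction must be in [0, 1]")
    cfg = config or ColonyRenderConfig()
    n = cfg.image_size
    shape = (n, n)
    cy = cx = (n - 1) / 2.0
    well_r = n / 2.0 - cfg.well_margin
    yy, xx = np.mgrid[0:n, 0:n]
    disk_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= well_r ** 2
    disk_px = int(disk_mask.sum())
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(88,)))

    if covered_fraction == 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif covered_fraction == 1.0:
        mask = disk_mask.copy()
    else:
        if n_colonies < 1:
            raise ValueError("n_colonies must be >= 1 for a partially covered well")
        rr = well_r - 8.0
        ang = rng.uniform(0, 2 * np.pi, size=n_colonies)
        rad = rr * np.sqrt(rng.uniform(0, 1, size=n_colonies))
        centers = np.column_stack([cy + rad * np.sin(ang), cx + rad * np.cos(ang)])
        sigma = np.sqrt(np.log(1 + cfg.colony_radius_cv ** 2))
        radii = cfg.colony_radius_mean * rng.lognormal(-sigma ** 2 / 2, sigma, size=n_colonies)

        def realized(scale: float) -> float:
            return _colony_mask(centers, radii, scale, shape, disk_mask).sum() / disk_px

        lo, hi = 1e-3, 1.0
        while realized(hi) < covered_fraction and hi < 200:
            hi *= 2.0
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if realized(mid) < covered_fraction:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-6 * hi:
                break
        mask = _colony_mask(centers, radii, hi, shape, disk_mask)

    realized_fraction = mask.sum() / disk_px
    img = np.full(shape, cfg.outside_level, dtype=float)
    img[disk_mask] = cfg.background_level
    img[mask] = cfg.stain_level
    if cfg.smooth_sigma > 0:
        from skimage.filters import gaussian
        img = gaussian(img, sigma=cfg.smooth_sigma, preserve_range=True)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0, cfg.noise_sigma, size=shape)
    img = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
    return ColonyImage(
        image=img, mask=mask, well_center=(cy, cx), well_radius=well_r,
        requested_fraction=float(covered_fraction),
        realized_fraction=float(realized_fraction), n_colonies=n_colonies,
    )
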