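"""Screen-level statistics: plate QC, gene scoring, hit calling, concordance.

Per-gene scores aggregate triplicate wells.  Categories I and II share one
statistic — the fold-change of the BAX-puncta-positive fraction against
the same-plate nontargeting-control mean (hits score roughly threefold to
fivefold above or below controls) — ranked descending for category I and
ascending for category II.  Category III is the raw percentage of
BAX/OMI double-positive cells, ranked descending.  Primary hits are the
top decile of the rank-sorted score distribution; secondary confirmation
requires at least three of the four individual siRNAs from a pool to
reproduce the primary call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phenotype import PhenotypeLabel, WellSummary

log = logging.getLogger(__name__)

CATEGORIES = ("I", "II", "III")
#: sort direction per category: descending for increased phenotypes
DESCENDING = {"I": True, "II": False, "III": True}


def compute_zprime(positive_values: Sequence[float],
                   negative_values: Sequence[float]) -> float:
    """Z' assay-window statistic: 1 - 3(s_pos + s_neg) / |m_pos - m_neg|.

    Sample standard deviations (ddof=1).  Raises if either control set has
    fewer than two values or the means coincide (Z' undefined).
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values in each control set")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("control means are equal; Z' undefined")
    # constant controls have exactly zero spread (avoids mean-roundoff dust)
    s_p = 0.0 if np.ptp(pos) == 0 else float(pos.std(ddof=1))
    s_n = 0.0 if np.ptp(neg) == 0 else float(neg.std(ddof=1))
    return float(1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n))


@dataclass
class GeneScore:
    gene: str
    n_replicates: int
    bax_fold: float  # categories I/II statistic
    bax_fold_sem: float
    dp_pct: float  # category III statistic (% double-positive)
    dp_pct_sem: float

    def statistic(self, category: str) -> float:
        if category in ("I", "II"):
            return self.bax_fold
        if category == "III":
            return self.dp_pct
        raise ValueError(f"unknown category {category!r}")


@dataclass
class HitCall:
    gene: str
    category: str
    score: float
    rank: int
    tail_fraction: float
    tie_degenerate: bool = False


@dataclass
class SecondaryResult:
    gene: str
    sirna_hits: list  # 4 booleans
    n_concordant: int
    confirmed: bool


def _sem(values: np.ndarray) -> float:
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def score_genes(
    summaries: Sequence[WellSummary],
    plate_map: pd.DataFrame,
) -> list[GeneScore]:
    """Aggregate well summaries into per-gene triplicate scores.

    For each replicate plate the BAX-positive fraction of a gene's well is
    divided by that plate's mean over nontargeting negative-control wells;
    the double-positive percentage is taken as-is.  Replicates are then
    averaged (mean and SEM = sd/sqrt(n)); invalid wells are skipped with
    the replicate count decremented, and genes with no valid replicate are
    excluded with a logged warning.
    """
    by_well = {}
    for s in summaries:
        by_well.setdefault(s.well_id, []).append(s)

    def well_summary(plate_id: str, well: str) -> Optional[WellSummary]:
        # summaries may be per (plate_id, well) via well_id "P01R1/B03" or plain well
        for key in (f"{plate_id}/{well}", well):
            if key in by_well:
                for s in by_well[key]:
                    return s
        return None

    bp = PhenotypeLabel.BAX_POSITIVE
    dp = PhenotypeLabel.DOUBLE_POSITIVE

    neg_means: dict[str, float] = {}
    for plate_id, grp in plate_map[plate_map.role == "NEG_CONTROL"].groupby("plate_id"):
        vals = []
        for row in grp.itertuples(index=False):
            s = well_summary(plate_id, row.well)
            if s is not None and s.valid:
                vals.append(s.fractions[bp])
        if len(vals) < 2:
            raise ValueError(f"plate {plate_id} has fewer than 2 valid NEG_CONTROL wells")
        neg_means[plate_id] = float(np.mean(vals))

    per_gene: dict[str, dict[str, list[float]]] = {}
    samples = plate_map[plate_map.role == "SAMPLE"]
    for row in samples.itertuples(index=False):
        s = well_summary(row.plate_id, row.well)
        if s is None or not s.valid:
            continue
        ctrl = neg_means[row.plate_id]
        if ctrl <= 0:
            log.warning("plate %s control mean is 0; skipping its wells", row.plate_id)
            continue
        d = per_gene.setdefault(row.gene, {"fold": [], "dp": []})
        d["fold"].append(s.fractions[bp] / ctrl)
        d["dp"].append(100.0 * s.fractions[dp])

    scores = []
    for gene in sorted(per_gene):
        folds = np.array(per_gene[gene]["fold"])
        dps = np.array(per_gene[gene]["dp"])
        scores.append(
            GeneScore(
                gene=gene,
                n_replicates=int(folds.size),
                bax_fold=float(folds.mean()),
                bax_fold_sem=_sem(folds),
                dp_pct=float(dps.mean()),
                dp_pct_sem=_sem(dps),
            )
        )
    skipped = set(samples.gene) - set(per_gene)
    for gene in sorted(skipped):
        log.warning("gene %s has no valid replicate wells; excluded", gene)
    return scores


def call_primary_hits(
    scores: Sequence[GeneScore],
    category: str,
    tail_fraction: float = 0.10,
    mode: str = "rank",
) -> list[HitCall]:
    """Select the tail of the score distribution as primary hits.

    ``mode='rank'`` (default) takes the top ``floor(tail_fraction * n)``
    genes by rank — descending score for categories I and III, ascending
    for II — with ties at the cutoff broken by lexicographic gene
    identifier.  ``mode='range'`` instead takes every gene whose score
    lies in the extreme ``tail_fraction`` of the numeric score range.
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if not scores:
        raise ValueError("need at least one scored gene")
    desc = DESCENDING[category]
    stats = [(s.statistic(category), s.gene) for s in scores]
    key = (lambda t: (-t[0], t[1])) if desc else (lambda t: (t[0], t[1]))
    ranked = sorted(stats, key=key)

    if mode == "rank":
        n_hits = int(math.floor(tail_fraction * len(ranked)))
        chosen = ranked[:n_hits]
    elif mode == "range":
        vals = [v for v, _ in stats]
        lo, hi = min(vals), max(vals)
        if desc:
            cut = hi - tail_fraction * (hi - lo)
            chosen = [t for t in ranked if t[0] >= cut]
        else:
            cut = lo + tail_fraction * (hi - lo)
            chosen = [t for t in ranked if t[0] <= cut]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    boundary_tied = (
        len(chosen) > 0
        and len(chosen) < len(ranked)
        and ranked[len(chosen) - 1][0] == ranked[len(chosen)][0]
    )
    return [
        HitCall(gene=g, category=category, score=v, rank=i + 1,
                tail_fraction=tail_fraction,
                tie_degenerate=boundary_tied and v == chosen[-1][0])
        for i, (v, g) in enumerate(chosen)
    ]


def threshold_rule_from_hits(hits: Sequence[HitCall], category: str) -> Callable[[float], bool]:
    """Hit/miss rule at the primary screen's realized score cutoff."""
    if not hits:
        raise ValueError("empty hit list")
    cutoff = hits[-1].score
    if DESCENDING[category]:
        return lambda score: score >= cutoff
    return lambda score: score <= cutoff


def confirm_secondary(
    per_sirna_scores: Mapping[str, Sequence[Optional[float]]],
    hit_rule: Callable[[float], bool],
    min_concordant: int = 3,
) -> list[SecondaryResult]:
    """Apply the >=3-of-4 individual-siRNA concordance filter.

    Each of a gene's four deconvolved siRNAs is marked hit/miss by the
    same rule and thresholds used in the primary category; missing scores
    count as non-concordant.  A gene is confirmed iff at least
    ``min_concordant`` siRNAs are hits.
    """
    results = []
    for gene in sorted(per_sirna_scores):
        raw = list(per_sirna_scores[gene])
        if len(raw) != 4:
            raise ValueError(f"gene {gene} has {len(raw)} siRNA scores; expected 4")
        flags = [bool(s is not None and hit_rule(s)) for s in raw]
        n = sum(flags)
        results.append(
            SecondaryResult(gene=gene, sirna_hits=flags, n_concordant=n,
                            confirmed=n >= min_concordant)
        )
    return results


def gene_scores_from_table(df: pd.DataFrame) -> list[GeneScore]:
    """Aggregate a simulated score table (gene, replicate, bax_fold, dp_pct)."""
    scores = []
    for gene, grp in df.groupby("gene", sort=True):
        folds = grp["bax_fold"].to_numpy(dtype=float)
        dps = grp["dp_pct"].to_numpy(dtype=float)
        scores.append(
            GeneScore(
                gene=str(gene), n_replicates=len(grp),
                bax_fold=float(folds.mean()), bax_fold_sem=_sem(folds),
                dp_pct=float(dps.mean()), dp_pct_sem=_sem(dps),
            )
        )
    return scores
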