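"""Orphan (taxonomically restricted) gene analysis of the DE response.

Orphan status — no homolog cluster in any other species of the comparison
set — arrives as a precomputed annotation flag.  This module quantifies the
orphan share of DEG sets and tests whether orphans are enriched in the
early response stage or differ between induced and repressed genes.  All
tests are the exact hypergeometric 2x2 test of :func:`enrich.fisher_2x2`.

For the stage contrast each DEG is assigned to its earliest significant
control-vs-t comparison, which makes the early (1, 3 h) and later
(8, 24 h) sets disjoint as a 2x2 test requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .dataset import pair_label
from .degcall import INDUCED, REPRESSED, DEGResults
from .enrich import fisher_2x2

__all__ = [
    "OrphanFraction",
    "orphan_fraction",
    "earliest_response_sets",
    "stage_enrichment_test",
    "direction_enrichment_test",
    "OrphanStageAnalysis",
    "OrphanStageResult",
]

EARLY_TIME_POINTS = (1.0, 3.0)


class OrphanFraction(NamedTuple):
    n_orphan: int
    n_total: int
    percent: float | None


class OrphanTest(NamedTuple):
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float


def _round_half_away(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _orphan_lookup(annotation) -> pd.Series:
    if isinstance(annotation, pd.DataFrame):
        return annotation["orphan"].astype(bool)
    return pd.Series(annotation).astype(bool)


def orphan_fraction(genes: Iterable[str], annotation, decimals: int = 0) -> OrphanFraction:
    """Count orphans in a gene set and report the percentage.

    The percentage is rounded half-away-from-zero to ``decimals`` places
    (the convention of printed percentages); an empty set yields an
    explicit empty result with ``percent=None``.
    """
    genes = list(genes)
    if not genes:
        return OrphanFraction(0, 0, None)
    orphan = _orphan_lookup(annotation)
    missing = [g for g in genes if g not in orphan.index]
    if missing:
        raise KeyError(f"annotation lacks gene(s): {missing[:5]}")
    n_orphan = int(orphan.loc[genes].sum())
    percent = _round_half_away(100.0 * n_orphan / len(genes), decimals)
    return OrphanFraction(n_orphan, len(genes), percent)


def earliest_response_sets(
    results: DEGResults, early_time_points: tuple[float, ...] = EARLY_TIME_POINTS
) -> tuple[set[str], set[str]]:
    """Split DEGs into disjoint early/later sets by earliest significant comparison.

    A gene's stage is the earliest time point t for which the control-vs-t
    comparison called it; genes first responding at a time point in
    ``early_time_points`` form the early set, the rest the later set.
    """
    early: set[str] = set()
    later: set[str] = set()
    assigned: set[str] = set()
    for pair in sorted(results.control_pairs, key=lambda p: p[1]):
        new = results.deg_genes(pair) - assigned
        if pair[1] in {float(t) for t in early_time_points}:
            early |= new
        else:
            later |= new
        assigned |= new
    return early, later


def _two_by_two(set_a: set[str], set_b: set[str], annotation) -> tuple[int, int, int, int]:
    if set_a & set_b:
        raise ValueError("gene sets must be disjoint for a 2x2 contrast")
    orphan = _orphan_lookup(annotation)
    fa = orphan_fraction(set_a, annotation)
    fb = orphan_fraction(set_b, annotation)
    return fa.n_orphan, fa.n_total - fa.n_orphan, fb.n_orphan, fb.n_total - fb.n_orphan


def stage_enrichment_test(early_set, later_set, annotation) -> OrphanTest:
    """One-sided exact test that the orphan share is higher among early responders."""
    a, b, c, d = _two_by_two(set(early_set), set(later_set), annotation)
    res = fisher_2x2(a, b, c, d)
    return OrphanTest(((a, b), (c, d)), res.p_over)


def direction_enrichment_test(induced_set, repressed_set, annotation) -> OrphanTest:
    """Two-sided exact test comparing orphan shares of induced vs repressed genes."""
    a, b, c, d = _two_by_two(set(induced_set), set(repressed_set), annotation)
    res = fisher_2x2(a, b, c, d)
    return OrphanTest(((a, b), (c, d)), res.p_two_sided)


@dataclass
class OrphanStageResult:
    """Per-time-point orphan tallies plus the stage and direction contrasts."""

    per_timepoint: pd.DataFrame
    stage_test: OrphanTest
    direction_test: OrphanTest | None
    persistent_fraction: OrphanFraction
    overall_fraction: OrphanFraction

    def summary(self) -> str:
        lines = [self.per_timepoint.to_string(index=False), ""]
        ov = self.overall_fraction
        lines.append(
            f"Orphans among all DEGs: {ov.n_orphan}/{ov.n_total}"
            + (f" ({ov.percent:g}%)" if ov.percent is not None else "")
        )
        (a, b), (c, d) = self.stage_test.table
        lines.append(
            f"Early vs later orphan enrichment (one-sided): table [[{a},{b}],[{c},{d}]], "
            f"p = {self.stage_test.p:.3g}"
        )
        if self.direction_test is not None:
            (a, b), (c, d) = self.direction_test.table
            lines.append(
                f"Induced vs repressed orphan share (two-sided): table [[{a},{b}],[{c},{d}]], "
                f"p = {self.direction_test.p:.3g}"
            )
        pf = self.persistent_fraction
        if pf.n_total:
            lines.append(
                f"Orphans among persistently induced genes: {pf.n_orphan}/{pf.n_total} ({pf.percent:g}%)"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.per_timepoint.to_csv(path, sep="\t", index=False)


class OrphanStageAnalysis:
    """Orphan-gene analysis of a fitted DE result.

    ``fit()`` tallies orphan counts per control-vs-t comparison (split by
    direction), runs the early-vs-later stage enrichment test on the
    earliest-response partition, contrasts induced vs repressed genes
    (genes induced at one time point and repressed at another are dropped
    from that contrast), and reports the orphan share of persistently
    induced genes.
    """

    def __init__(
        self,
        results: DEGResults,
        annotation,
        early_time_points: tuple[float, ...] = EARLY_TIME_POINTS,
    ) -> None:
        self.results = results
        self.annotation = annotation
        self.early_time_points = early_time_points

    def fit(self) -> OrphanStageResult:
        res = self.results
        ann = self.annotation
        rows = []
        for pair in res.control_pairs:
            genes = res.deg_genes(pair)
            ind = res.deg_genes(pair, INDUCED)
            rep = res.deg_genes(pair, REPRESSED)
            tot = orphan_fraction(genes, ann)
            oi = orphan_fraction(ind, ann)
            orp = orphan_fraction(rep, ann)
            rows.append(
                {
                    "pair": pair_label(*pair),
                    "n_deg": tot.n_total,
                    "n_orphan": tot.n_orphan,
                    "percent_orphan": tot.percent,
                    "n_induced": oi.n_total,
                    "n_orphan_induced": oi.n_orphan,
                    "percent_orphan_induced": oi.percent,
                    "n_repressed": orp.n_total,
                    "n_orphan_repressed": orp.n_orphan,
                    "percent_orphan_repressed": orp.percent,
                }
            )
        per_tp = pd.DataFrame(rows)

        early, later = earliest_response_sets(res, self.early_time_points)
        stage = stage_enrichment_test(early, later, ann)

        induced_any: set[str] = set()
        repressed_any: set[str] = set()
        for pair in res.control_pairs:
            induced_any |= res.deg_genes(pair, INDUCED)
            repressed_any |= res.deg_genes(pair, REPRESSED)
        both = induced_any & repressed_any
        direction = None
        if induced_any - both or repressed_any - both:
            direction = direction_enrichment_test(induced_any - both, repressed_any - both, ann)

        persist = res.classify_persistence()
        persistent_genes = set(persist.index[persist["persistent_induced"]])
        return OrphanStageResult(
            per_timepoint=per_tp,
            stage_test=stage,
            direction_test=direction,
            persistent_fraction=orphan_fraction(persistent_genes, ann, decimals=2),
            overall_fraction=orphan_fraction(res.any_deg_genes(), ann),
        )
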