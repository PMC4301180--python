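"""Fisher's-exact term enrichment and stage partitioning of the time course.

Over/under-representation of annotation terms (typically GO) in a DEG set
against a gene universe is tested with the exact hypergeometric 2x2 test;
the two-sided p-value follows the conventional minimum-likelihood rule
(sum the probabilities of all tables with the observed margins whose point
probability does not exceed that of the observed table).  The time course
is partitioned into early (1, 3 h), intermediate (8 h) and late (24 h)
response stages whose gene sets are unions of the control-vs-t DEG calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .degcall import INDUCED, REPRESSED, DEGResults, bh_adjust

__all__ = [
    "FisherResult",
    "fisher_2x2",
    "enrich_terms",
    "StagePartition",
    "partition_stages",
    "DEFAULT_STAGE_MAP",
]

DEFAULT_STAGE_MAP: dict[float, str] = {1.0: "early", 3.0: "early", 8.0: "intermediate", 24.0: "late"}

_REL_TOL = 1e-7  # relative slack in the point-probability comparison of the two-sided rule


class FisherResult(NamedTuple):
    p_two_sided: float
    p_over: float
    p_under: float


def fisher_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Exact test of a 2x2 table (in-set & term, in-set & no term, out & term, out & no term).

    Returns the two-sided (minimum-likelihood rule), upper-tail (over-
    representation) and lower-tail (under-representation) p-values.  Tails
    are exact hypergeometric sums with the table's margins fixed.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    total = a + b + c + d
    if total == 0:
        return FisherResult(1.0, 1.0, 1.0)
    n_term = a + c
    n_set = a + b
    dist = stats.hypergeom(total, n_term, n_set)
    lo = max(0, n_set - (total - n_term))
    hi = min(n_set, n_term)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p_over = float(pmf[support >= a].sum())
    p_under = float(pmf[support <= a].sum())
    p_two = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return FisherResult(min(p_two, 1.0), min(p_over, 1.0), min(p_under, 1.0))


def _as_term_map(annotation) -> Mapping[str, frozenset[str]]:
    """Accept a gene->terms mapping, an annotation DataFrame with a
    ``go_terms`` column, or a two-column (gene_id, term) association frame."""
    if isinstance(annotation, pd.DataFrame):
        if "go_terms" in annotation.columns:
            return {g: frozenset(t) for g, t in annotation["go_terms"].items()}
        gcol, tcol = annotation.columns[:2]
        out: dict[str, set[str]] = {}
        for g, t in zip(annotation[gcol], annotation[tcol]):
            out.setdefault(g, set()).add(t)
        return {g: frozenset(t) for g, t in out.items()}
    return {g: frozenset(t) for g, t in dict(annotation).items()}


def enrich_terms(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every annotated term for over/under-representation in ``gene_set``.

    The universe defines the background; genes may carry zero terms.  BH
    correction runs across terms; the direction of a BH-significant term is
    the smaller one-tail.  Returns one row per term, sorted by adjusted p.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene set must be contained in the universe")
    terms_of = _as_term_map(annotation)
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in terms_of.get(g, ()):
            term_genes.setdefault(t, set()).add(g)

    n_set = len(gene_set)
    n_uni = len(universe)
    rows = []
    for term, genes in term_genes.items():
        a = len(genes & gene_set)
        b = n_set - a
        c = len(genes) - a
        d = (n_uni - n_set) - c
        res = fisher_2x2(a, b, c, d)
        rows.append((term, a, b, c, d, *res))
    out = pd.DataFrame(
        rows,
        columns=["term", "a", "b", "c", "d", "p_two_sided", "p_over", "p_under"],
    )
    if len(out):
        out["p_bh"] = bh_adjust(out["p_two_sided"])
        sig = out["p_bh"] < alpha
        out["direction"] = np.where(
            sig, np.where(out["p_over"] < out["p_under"], "over", "under"), "none"
        )
        out = out.sort_values("p_bh", kind="stable").reset_index(drop=True)
    else:
        out["p_bh"] = []
        out["direction"] = []
    return out


@dataclass
class StagePartition:
    """Assignment of time points to response stages with the derived gene sets.

    ``sets[stage]`` is the union of genes called DEG in the control-vs-t
    comparison for any t of the stage; induced/repressed subsets are carried
    along.  Sets of different stages may overlap (a gene can respond at an
    early and a late time point).
    """

    stage_map: dict[float, str]
    sets: dict[str, set[str]]
    induced: dict[str, set[str]]
    repressed: dict[str, set[str]]

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.stage_map.values():
            if s not in seen:
                seen.append(s)
        return seen


def partition_stages(
    results: DEGResults, stage_map: Mapping[float, str] | None = None
) -> StagePartition:
    """Partition the control-vs-t DEG calls into response-stage gene sets."""
    if stage_map is None:
        stage_map = DEFAULT_STAGE_MAP
    stage_map = {float(t): s for t, s in stage_map.items()}
    non_control = [t for t in results.time_points if t != results.control]
    missing = [t for t in non_control if t not in stage_map]
    if missing:
        raise ValueError(f"stage map misses time point(s): {missing}")

    sets: dict[str, set[str]] = {}
    induced: dict[str, set[str]] = {}
    repressed: dict[str, set[str]] = {}
    for s in stage_map.values():
        sets.setdefault(s, set())
        induced.setdefault(s, set())
        repressed.setdefault(s, set())
    for pair in results.control_pairs:
        stage = stage_map[pair[1]]
        sets[stage] |= results.deg_genes(pair)
        induced[stage] |= results.deg_genes(pair, INDUCED)
        repressed[stage] |= results.deg_genes(pair, REPRESSED)
    return StagePartition(stage_map=stage_map, sets=sets, induced=induced, repressed=repressed)
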