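"""Comparative process-specialization classifier for TAP families.

Transcription-associated protein (TAP) families from two species are pooled
and each member gene is tabulated into GO biological-process classes:
developmental, stimulus/stress, or both (genes without a class annotation
count toward family totals but not toward the class tabulation).  Each
family is then tested for association with each process side by a one-sided
(enrichment) Fisher's exact test against the background of all other
annotated TAP genes, with a single BH correction across every family x
class test of the run.

Families are assigned one of three annotation quality classes:
1 — the best class is significant after BH correction;
2 — only the raw p is significant;
3 — no significance; the class with the larger annotated member count is
assigned, with ties declared unspecialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .degcall import bh_adjust
from .enrich import fisher_2x2
from .go_classes import (
    BOTH,
    DEVELOPMENTAL,
    PROCESS_CLASSES,
    STIMULUS_STRESS,
    UNANNOTATED,
    UNSPECIALIZED,
    process_class,
)

__all__ = [
    "combine_tap_annotations",
    "gene_table_from_annotation",
    "tabulate_families",
    "classify_family",
    "classify_all",
    "TAPSpecialization",
    "TAPClassificationResults",
]


def combine_tap_annotations(
    species_a: pd.DataFrame,
    species_b: pd.DataFrame,
    classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pool two per-species TAP membership tables into one gene table.

    Each input holds columns ``gene_id``, ``species`` and ``tap_family``
    (and optionally ``process_class``).  ``classes``, if given, maps
    ``gene_id`` to ``class`` values ``developmental``/``stimulus``/
    ``stress``; a gene annotated to both sides becomes class ``both``,
    genes absent from the mapping stay ``unannotated``.  A gene assigned to
    more than one family is an error.
    """
    pooled = pd.concat([species_a, species_b], ignore_index=True)
    for col in ("gene_id", "species", "tap_family"):
        if col not in pooled.columns:
            raise ValueError(f"TAP tables need a {col!r} column")
    fam_per_gene = pooled.groupby(["species", "gene_id"])["tap_family"].nunique()
    if (fam_per_gene > 1).any():
        bad = fam_per_gene.index[fam_per_gene > 1][:5].tolist()
        raise ValueError(f"gene(s) assigned to more than one family: {bad}")
    pooled = pooled.drop_duplicates(["species", "gene_id"]).reset_index(drop=True)

    if "process_class" not in pooled.columns:
        pooled["process_class"] = UNANNOTATED
    if classes is not None:
        side_map = {"developmental": "dev", "stimulus": "stim", "stress": "stim"}
        sides: dict[str, set[str]] = {}
        for g, cls in zip(classes["gene_id"], classes["class"]):
            if cls not in side_map:
                raise ValueError(f"unknown process class {cls!r}")
            sides.setdefault(g, set()).add(side_map[cls])
        def _cls(g):
            s = sides.get(g)
            if not s:
                return UNANNOTATED
            if s == {"dev"}:
                return DEVELOPMENTAL
            if s == {"stim"}:
                return STIMULUS_STRESS
            return BOTH
        pooled["process_class"] = pooled["gene_id"].map(_cls)
    return pooled[["gene_id", "species", "tap_family", "process_class"]]


def gene_table_from_annotation(annotation: pd.DataFrame, species: str) -> pd.DataFrame:
    """Build a per-species TAP gene table from a synthetic annotation table."""
    tap = annotation[annotation["tap_family"].notna()]
    return pd.DataFrame(
        {
            "gene_id": tap.index,
            "species": species,
            "tap_family": tap["tap_family"].to_numpy(),
            "process_class": [process_class(t) for t in tap["go_terms"]],
        }
    )


def tabulate_families(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per-family class tabulation (one row per family).

    Side counts follow the rule that a ``both`` gene is evidence for each
    side: ``n_developmental = dev-only + both`` and likewise for
    stimulus/stress.  ``n_annotated`` excludes unannotated members.
    """
    rows = []
    for family, sub in gene_table.groupby("tap_family", sort=True):
        cls = sub["process_class"]
        n_dev_only = int((cls == DEVELOPMENTAL).sum())
        n_stim_only = int((cls == STIMULUS_STRESS).sum())
        n_both = int((cls == BOTH).sum())
        rows.append(
            {
                "tap_family": family,
                "n_total": len(sub),
                "n_annotated": n_dev_only + n_stim_only + n_both,
                "n_developmental_only": n_dev_only,
                "n_stimulus_only": n_stim_only,
                "n_both": n_both,
                "n_developmental": n_dev_only + n_both,
                "n_stimulus_stress": n_stim_only + n_both,
            }
        )
    return pd.DataFrame(rows).set_index("tap_family")


_SIDE_COL = {DEVELOPMENTAL: "n_developmental", STIMULUS_STRESS: "n_stimulus_stress"}


def classify_family(
    family_counts: pd.Series,
    background_counts: pd.Series,
    alpha: float = 0.05,
    adjusted: dict[str, float] | None = None,
) -> dict:
    """Classify one family given its tabulated counts and its background.

    ``family_counts``/``background_counts`` are rows of
    :func:`tabulate_families` (the background row is the column sum over
    all other families).  When ``adjusted`` carries BH-corrected p-values
    per class, the full three-tier quality assignment is made; otherwise
    only raw-p tiers (2/3) can be awarded.
    """
    if family_counts["n_total"] == 0:
        raise ValueError("cannot classify an empty family")
    raw: dict[str, float] = {}
    for cls in PROCESS_CLASSES:
        a = int(family_counts[_SIDE_COL[cls]])
        b = int(family_counts["n_annotated"]) - a
        c = int(background_counts[_SIDE_COL[cls]])
        d = int(background_counts["n_annotated"]) - c
        raw[cls] = fisher_2x2(a, b, c, d).p_over

    assigned, quality = None, 3
    if adjusted is not None and min(adjusted.values()) < alpha:
        assigned = min(adjusted, key=adjusted.get)
        quality = 1
    elif min(raw.values()) < alpha:
        assigned = min(raw, key=raw.get)
        quality = 2
    else:
        n_dev = int(family_counts["n_developmental"])
        n_stim = int(family_counts["n_stimulus_stress"])
        if n_dev == n_stim:
            assigned = UNSPECIALIZED
        else:
            assigned = DEVELOPMENTAL if n_dev > n_stim else STIMULUS_STRESS
    return {
        "assigned_class": assigned,
        "quality_class": quality,
        "p_developmental": raw[DEVELOPMENTAL],
        "p_stimulus_stress": raw[STIMULUS_STRESS],
    }


@dataclass
class TAPClassificationResults:
    """Per-family classification table plus summary counts.

    ``table`` has one row per family: tabulated counts, per-class raw and
    BH-adjusted one-sided p, assigned class, quality class (1/2/3) and the
    specialization flag.  ``summary_counts`` counts families per flag.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def summary_counts(self) -> dict[str, int]:
        return self.table["flag"].value_counts().to_dict()

    def summary(self) -> str:
        counts = self.summary_counts
        quality = self.table["quality_class"].value_counts().sort_index()
        lines = [
            f"TAP family specialization ({len(self.table)} families, alpha={self.alpha}):",
            "  " + ", ".join(f"{k}: {v}" for k, v in sorted(counts.items())),
            "  quality classes: "
            + ", ".join(f"class {q}: {n}" for q, n in quality.items()),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("tap_family").to_csv(path, sep="\t")


class TAPSpecialization:
    """Process-specialization model over a pooled TAP gene table.

    The Fisher background of each family is the complement of the family
    within the annotated TAP genes of both species.  BH correction spans
    all family x class tests of the run.
    """

    def __init__(self, gene_table: pd.DataFrame, alpha: float = 0.05) -> None:
        if gene_table["tap_family"].nunique() < 2:
            raise ValueError("need at least two TAP families")
        self.gene_table = gene_table
        self.alpha = float(alpha)

    def fit(self) -> TAPClassificationResults:
        tab = tabulate_families(self.gene_table)
        totals = tab.sum(axis=0)

        raw = pd.DataFrame(index=tab.index, columns=list(PROCESS_CLASSES), dtype=float)
        for family, row in tab.iterrows():
            background = totals - row
            for cls in PROCESS_CLASSES:
                a = int(row[_SIDE_COL[cls]])
                b = int(row["n_annotated"]) - a
                c = int(background[_SIDE_COL[cls]])
                d = int(background["n_annotated"]) - c
                raw.loc[family, cls] = fisher_2x2(a, b, c, d).p_over
        adj = pd.DataFrame(
            bh_adjust(raw.to_numpy().ravel()).reshape(raw.shape),
            index=raw.index,
            columns=raw.columns,
        )

        records = []
        for family, row in tab.iterrows():
            result = classify_family(
                row,
                totals - row,
                alpha=self.alpha,
                adjusted=adj.loc[family].to_dict(),
            )
            flag = result["assigned_class"]
            records.append(
                {
                    **row.to_dict(),
                    "p_developmental": raw.loc[family, DEVELOPMENTAL],
                    "p_stimulus_stress": raw.loc[family, STIMULUS_STRESS],
                    "p_bh_developmental": adj.loc[family, DEVELOPMENTAL],
                    "p_bh_stimulus_stress": adj.loc[family, STIMULUS_STRESS],
                    "assigned_class": result["assigned_class"],
                    "quality_class": result["quality_class"],
                    "flag": flag,
                }
            )
        table = pd.DataFrame(records, index=tab.index)
        return TAPClassificationResults(table=table, alpha=self.alpha)


def classify_all(gene_table: pd.DataFrame, alpha: float = 0.05) -> TAPClassificationResults:
    """Classify every family of a pooled TAP gene table."""
    return TAPSpecialization(gene_table, alpha=alpha).fit()
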