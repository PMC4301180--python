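"""Synthetic time-series transcriptome generator.

Emulates the statistical structure of a 5 time point x 3 replicate
whole-genome microarray cold-stress experiment: log-normal baseline
intensities, multiplicative replicate noise, a planted fraction of
differentially expressed genes whose effects switch on at an early
(1, 3 h), intermediate (8 h) or late (24 h) stage and persist as step
functions, TAP families with process-class-biased GO labels, and an
orphan-gene fraction that can be enriched among early responders.

Every draw flows from a single integer seed, so identical configurations
produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, format_timepoint
from .go_classes import (
    GO_DEVELOPMENTAL,
    GO_RESPONSE_TO_STIMULUS,
    GO_RESPONSE_TO_STRESS,
)

__all__ = [
    "StageSpec",
    "SimulationConfig",
    "generate_dataset",
    "inject_effects",
    "assign_annotations",
    "simulate_tap_gene_table",
]

_MIN_EFFECT_LOG2 = 0.25  # floor on planted |effect|; keeps planted genes distinguishable from pure noise


@dataclass(frozen=True)
class StageSpec:
    """Planted-effect profile for one response stage.

    fraction: share of DE genes whose first response falls in this stage.
    effect_mean_log2 / effect_sd_log2: normal distribution of the planted
    |log2 effect| (truncated below at 0.25).
    induced_fraction: probability the effect is positive (induction).
    """

    fraction: float
    effect_mean_log2: float = 1.8
    effect_sd_log2: float = 0.6
    induced_fraction: float = 0.6


def _default_stage_profile() -> dict[str, StageSpec]:
    # first-response shares approximate the observed accumulation of DEGs
    # over the time course (few by 3 h, the bulk from 8 h on)
    return {
        "early": StageSpec(0.08, 1.5, 0.6, 0.65),
        "intermediate": StageSpec(0.45, 1.8, 0.6, 0.52),
        "late": StageSpec(0.47, 2.0, 0.6, 0.63),
    }


def _default_stage_time_points() -> dict[str, tuple[float, ...]]:
    return {"early": (1.0, 3.0), "intermediate": (8.0,), "late": (24.0,)}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment; validated on construction."""

    n_genes: int = 10_000
    time_points: tuple[float, ...] = (0.0, 1.0, 3.0, 8.0, 24.0)
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.25
    de_fraction: float = 0.116
    stage_profile: dict[str, StageSpec] = field(default_factory=_default_stage_profile)
    stage_time_points: dict[str, tuple[float, ...]] = field(
        default_factory=_default_stage_time_points
    )
    transient_fraction: float = 0.0
    tap_family_sizes: Sequence[int] | None = None
    n_tap_families: int = 48
    class_bias: float | Sequence[float] | None = None
    p_both_class: float = 0.10
    p_unannotated_tap: float = 0.15
    n_go_terms: int = 40
    go_terms_per_gene: float = 2.0
    stress_term_p_de: float = 0.30
    orphan_fraction: float = 0.12
    orphan_early_enrichment: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if len(self.time_points) < 2:
            raise ValueError("need at least two time points")
        for name, value in [
            ("de_fraction", self.de_fraction),
            ("orphan_fraction", self.orphan_fraction),
            ("transient_fraction", self.transient_fraction),
            ("p_both_class", self.p_both_class),
            ("p_unannotated_tap", self.p_unannotated_tap),
            ("stress_term_p_de", self.stress_term_p_de),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.orphan_early_enrichment < 0:
            raise ValueError("orphan_early_enrichment must be non-negative")
        total = sum(s.fraction for s in self.stage_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage_profile fractions must sum to 1, got {total}")
        for stage, spec in self.stage_profile.items():
            if not 0.0 <= spec.fraction <= 1.0:
                raise ValueError(f"stage fraction for {stage!r} outside [0, 1]")
            if not 0.0 <= spec.induced_fraction <= 1.0:
                raise ValueError(f"induced_fraction for {stage!r} outside [0, 1]")
            if stage not in self.stage_time_points:
                raise ValueError(f"stage {stage!r} has no assigned time points")
            for t in self.stage_time_points[stage]:
                if float(t) not in {float(x) for x in self.time_points[1:]}:
                    raise ValueError(
                        f"stage {stage!r} references time point {t} absent from the design"
                    )

    @property
    def control(self) -> float:
        return float(self.time_points[0])

    @property
    def stages(self) -> list[str]:
        return list(self.stage_profile)


def _gene_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"g{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def _sample_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.time_points:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"t{format_timepoint(t)}h_r{r}", float(t), r))
    design = pd.DataFrame(rows, columns=["sample_id", "time_point_h", "replicate"])
    return design.set_index("sample_id")


def _draw_truth(config: SimulationConfig, gene_ids: pd.Index, rng: np.random.Generator) -> pd.DataFrame:
    n = len(gene_ids)
    is_de = rng.random(n) < config.de_fraction
    stages = np.array(config.stages, dtype=object)
    fractions = np.array([config.stage_profile[s].fraction for s in stages])
    stage_idx = rng.choice(len(stages), size=n, p=fractions)

    truth = pd.DataFrame(index=gene_ids)
    truth["is_de"] = is_de
    truth["stage"] = np.where(is_de, stages[stage_idx], None)
    first_tp = np.full(n, np.nan)
    direction = np.zeros(n, dtype=int)
    magnitude = np.zeros(n)
    transient = rng.random(n) < config.transient_fraction
    for i in np.flatnonzero(is_de):
        stage = stages[stage_idx[i]]
        spec = config.stage_profile[stage]
        tps = config.stage_time_points[stage]
        first_tp[i] = float(tps[rng.integers(len(tps))])
        direction[i] = 1 if rng.random() < spec.induced_fraction else -1
        magnitude[i] = max(
            _MIN_EFFECT_LOG2, rng.normal(spec.effect_mean_log2, spec.effect_sd_log2)
        )
    truth["first_time_point"] = first_tp
    truth["direction"] = direction
    truth["magnitude_log2"] = magnitude
    truth["transient"] = np.where(is_de, transient, False)

    stage_of_tp = {
        float(t): s for s, tps in config.stage_time_points.items() for t in tps
    }
    for t in config.time_points[1:]:
        t = float(t)
        active = is_de & (first_tp <= t)
        if config.transient_fraction > 0:
            # a transient responder carries its effect only at time points of its own stage
            same_stage = np.array(
                [
                    (s is not None) and (stage_of_tp.get(t) == s)
                    for s in truth["stage"]
                ]
            )
            active = active & (~truth["transient"].to_numpy() | same_stage)
        truth[f"effect_log2_{format_timepoint(t)}h"] = np.where(
            active, direction * magnitude, 0.0
        )
    return truth


def inject_effects(
    log2_matrix: pd.DataFrame, design: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Add planted log2 effects to the designated time-point groups.

    ``log2_matrix`` is genes x samples on the log2 scale (before
    exponentiation).  ``truth`` carries one ``effect_log2_{t}h`` column per
    non-control time point; genes absent from ``truth`` are left unchanged.
    """
    unknown = truth.index.difference(log2_matrix.index)
    if len(unknown):
        raise KeyError(f"truth table names genes absent from the matrix: {list(unknown[:5])}")
    out = log2_matrix.copy()
    effect_cols = [c for c in truth.columns if c.startswith("effect_log2_")]
    for col in effect_cols:
        t = float(col.removeprefix("effect_log2_").removesuffix("h"))
        samples = design.index[design["time_point_h"].astype(float) == t]
        if len(samples) == 0:
            continue
        effects = truth[col].reindex(out.index).fillna(0.0).to_numpy()
        out.loc[:, samples] = out.loc[:, samples].to_numpy() + effects[:, None]
    return out


def _family_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.tap_family_sizes is not None:
        sizes = np.asarray(list(config.tap_family_sizes), dtype=int)
        if (sizes < 1).any():
            raise ValueError("tap family sizes must be positive")
        return sizes
    return 2 + rng.poisson(2.0, size=config.n_tap_families)


def _family_biases(config: SimulationConfig, n_families: int, rng: np.random.Generator) -> np.ndarray:
    """Per-family probability that a member's class term falls on the stimulus/stress side."""
    if config.class_bias is None:
        # mixture mirroring the observed dominance of stress-specialized families
        kinds = rng.choice(3, size=n_families, p=[0.60, 0.36, 0.04])
        return np.choose(kinds, [0.85, 0.15, 0.50])
    if np.isscalar(config.class_bias):
        return np.full(n_families, float(config.class_bias))
    biases = np.asarray(list(config.class_bias), dtype=float)
    if len(biases) != n_families:
        raise ValueError("class_bias length must match the number of families")
    return biases


def assign_annotations(
    config: SimulationConfig,
    gene_ids: pd.Index,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw TAP family membership, class-biased GO labels and orphan flags.

    Orphan status is drawn at base rate ``orphan_fraction``; for genes whose
    planted stage is early the rate is multiplied by
    ``orphan_early_enrichment`` (capped at 1) and the rate of the remaining
    genes is lowered so the marginal orphan fraction stays at the base rate.
    """
    if gene_ids.has_duplicates:
        raise ValueError("gene ids must be unique")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(gene_ids)

    sizes = _family_sizes(config, rng)
    if sizes.sum() > n:
        raise ValueError("TAP families require more genes than the universe holds")
    biases = _family_biases(config, len(sizes), rng)
    tap_family = np.full(n, None, dtype=object)
    members = rng.choice(n, size=int(sizes.sum()), replace=False)
    fam_of_gene = np.full(n, -1)
    start = 0
    for f, size in enumerate(sizes):
        idx = members[start : start + size]
        tap_family[idx] = f"TAPfam{f + 1:02d}"
        fam_of_gene[idx] = f
        start += size

    # orphan flags: enriched among early responders, marginal rate preserved
    stage = truth["stage"].reindex(gene_ids)
    early = (stage == "early").to_numpy()
    n_early = int(early.sum())
    f = config.orphan_fraction
    p_early = min(1.0, f * config.orphan_early_enrichment)
    if n < 1 or n_early == n:
        p_other = p_early
    else:
        p_other = max(0.0, (f * n - p_early * n_early) / (n - n_early))
    orphan = rng.random(n) < np.where(early, p_early, p_other)

    # generic GO terms; planted responders carry the stress term more often
    pool = np.array([f"GO:9{i:06d}" for i in range(1, config.n_go_terms + 1)])
    counts = rng.poisson(config.go_terms_per_gene, size=n)
    is_de = truth["is_de"].reindex(gene_ids).fillna(False).to_numpy()
    go_terms: list[frozenset[str]] = []
    for i in range(n):
        terms = set(rng.choice(pool, size=min(counts[i], len(pool)), replace=False))
        if is_de[i] and rng.random() < config.stress_term_p_de:
            terms.add(GO_RESPONSE_TO_STRESS)
        if fam_of_gene[i] >= 0 and rng.random() >= config.p_unannotated_tap:
            bias = biases[fam_of_gene[i]]
            stim_side = rng.random() < bias
            if stim_side:
                terms.add(
                    GO_RESPONSE_TO_STIMULUS
                    if rng.random() < 0.5
                    else GO_RESPONSE_TO_STRESS
                )
            else:
                terms.add(GO_DEVELOPMENTAL)
            if rng.random() < config.p_both_class:
                terms.add(GO_DEVELOPMENTAL if stim_side else GO_RESPONSE_TO_STIMULUS)
        go_terms.append(frozenset(terms))

    return pd.DataFrame(
        {"tap_family": tap_family, "orphan": orphan, "go_terms": go_terms},
        index=gene_ids,
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic experiment.

    Returns ``(dataset, annotation, truth)``: the linear-scale expression
    dataset, the gene annotation table (TAP family, orphan flag, GO terms)
    and the truth table of planted effects.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_ids(config.n_genes)
    design = _sample_design(config)

    truth = _draw_truth(config, gene_ids, rng)

    base_mean = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    noise = rng.normal(0.0, config.noise_log2_sd, size=(config.n_genes, len(design)))
    log2 = pd.DataFrame(base_mean[:, None] + noise, index=gene_ids, columns=design.index)
    log2 = inject_effects(log2, design, truth)
    dataset = ExpressionDataset(matrix=np.exp2(log2), design=design)

    annotation = assign_annotations(config, gene_ids, truth, rng)
    return dataset, annotation, truth


def simulate_tap_gene_table(
    n_stimulus_families: int = 30,
    n_developmental_families: int = 15,
    n_neutral_families: int = 5,
    family_size: int = 20,
    bias: float = 0.9,
    p_unannotated: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-species pooled TAP gene table with planted family specialization.

    Each family's members carry a stimulus/stress class term with
    probability ``bias`` (stimulus-specialized families), ``1 - bias``
    (developmental families) or 0.5 (neutral families); members are split
    evenly between two species.  Returns the pooled gene table
    (gene_id, species, tap_family, process_class) and the planted class per
    family ('stimulus_or_stress', 'developmental' or 'unspecialized').
    """
    from .go_classes import BOTH, DEVELOPMENTAL, STIMULUS_STRESS, UNANNOTATED, UNSPECIALIZED

    rng = np.random.default_rng(seed)
    planted = (
        [STIMULUS_STRESS] * n_stimulus_families
        + [DEVELOPMENTAL] * n_developmental_families
        + [UNSPECIALIZED] * n_neutral_families
    )
    rows = []
    gid = 0
    for f, kind in enumerate(planted):
        p_stim = {STIMULUS_STRESS: bias, DEVELOPMENTAL: 1.0 - bias, UNSPECIALIZED: 0.5}[kind]
        for m in range(family_size):
            gid += 1
            if rng.random() < p_unannotated:
                cls = UNANNOTATED
            else:
                cls = STIMULUS_STRESS if rng.random() < p_stim else DEVELOPMENTAL
            species = "A" if m % 2 == 0 else "B"
            rows.append((f"{species}_g{gid:05d}", species, f"fam{f + 1:02d}", cls))
    table = pd.DataFrame(rows, columns=["gene_id", "species", "tap_family", "process_class"])
    truth = pd.Series(planted, index=[f"fam{f + 1:02d}" for f in range(len(planted))], name="planted_class")
    return table, truth
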