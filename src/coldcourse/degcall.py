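"""Differential-expression calling for K-group time-series intensity data.

The pipeline mirrors the classical microarray workflow: per-sample median
normalization, a per-gene one-way (K groups) ANOVA, Benjamini-Hochberg FDR
control across genes, Tukey HSD post-hoc tests for every pair of time
points with a within-gene Bonferroni correction, and effect sizes as linear
fold changes of group means.  A gene is a DEG for a time-point pair iff it
passes the gene-level BH gate (default FDR 0.05) and its Bonferroni-
corrected Tukey p for that pair is below the pairwise alpha.

All per-gene statistics are computed vectorized across the whole matrix;
the studentized-range tail probability is evaluated by Gauss-Legendre
quadrature so that tens of thousands of post-hoc p-values remain cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset, format_timepoint, pair_label

__all__ = [
    "median_normalize",
    "anova_k_groups",
    "bh_adjust",
    "studentized_range_sf",
    "tukey_pairwise_p",
    "fold_change",
    "ColdTimecourseDE",
    "DEGResults",
    "call_degs",
    "classify_persistence",
    "summarize_comparisons",
    "read_deg_table",
]

INDUCED = "induced"
REPRESSED = "repressed"
NONE = "none"
NOT_TESTED = "not_tested"


# ---------------------------------------------------------------------------
# normalization


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample so its median equals the grand median of sample medians.

    Scaling is multiplicative, so within-sample rank order is preserved.
    A sample whose median is zero cannot be rescaled and raises ``ValueError``.
    """
    matrix = pd.DataFrame(matrix)
    medians = matrix.median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0][:5])
        raise ValueError(f"sample(s) with non-positive median intensity: {bad}")
    grand = float(medians.median())
    return matrix * (grand / medians)


# ---------------------------------------------------------------------------
# per-gene one-way ANOVA (vectorized)


def _anova_matrix(X: np.ndarray, group_index: np.ndarray, k: int):
    """One-way fixed-effects ANOVA for every row of ``X``.

    Returns (F, p, group_means, msw) with degrees of freedom (k-1, N-k).
    Rows with zero within- and between-group variance get F = 0, p = 1;
    rows with zero within- but positive between-group variance get
    F = inf, p = 0.
    """
    n_obs = X.shape[1]
    sizes = np.bincount(group_index, minlength=k).astype(float)
    # group sums via one matmul
    indicator = np.zeros((n_obs, k))
    indicator[np.arange(n_obs), group_index] = 1.0
    gsums = X @ indicator
    gmeans = gsums / sizes
    grand = X.mean(axis=1)
    ssb = ((gmeans - grand[:, None]) ** 2 * sizes).sum(axis=1)
    sst = ((X - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    df_b, df_w = k - 1, n_obs - k
    msb = ssb / df_b
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0))
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df_b, df_w))
    p = np.where((msw == 0) & (msb == 0), 1.0, p)
    return F, p, gmeans, msw


def anova_k_groups(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over K groups of replicate observations.

    Returns the F statistic and its upper-tail p from F(k-1, N-k).  Groups
    with fewer than two observations are rejected; a gene with equal group
    means and zero within-group variance is reported with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group must hold at least two observations")
    X = np.concatenate(arrays)[None, :]
    idx = np.concatenate([np.full(a.size, i) for i, a in enumerate(arrays)])
    F, p, _, _ = _anova_matrix(X, idx, len(arrays))
    return float(F[0]), float(p[0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# studentized range upper tail (Tukey HSD)

_Z_NODES = 64
_S_NODES = 48
_CHUNK = 4000


def _range_cdf_factory(k: int):
    x, wt = leggauss(_Z_NODES)
    a, b = -8.5, 8.5
    z = 0.5 * (b - a) * x + 0.5 * (b + a)
    wz = 0.5 * (b - a) * wt * k * stats.norm.pdf(z)
    ndtr_z = special.ndtr(z)

    def cdf(w: np.ndarray) -> np.ndarray:
        inner = ndtr_z - special.ndtr(z - w[..., None])
        np.clip(inner, 0.0, None, out=inner)
        return np.sum(inner ** (k - 1) * wz, axis=-1)

    return cdf


def studentized_range_sf(q, k: int, df: float) -> np.ndarray | float:
    """Upper tail of the studentized range distribution Q(k, df).

    Evaluated by Gauss-Legendre quadrature of the double integral
    P(Q > q) = 1 - E_s[W(q s)] where W is the CDF of the range of k
    standard normals and s ~ sqrt(chi2_df / df); absolute accuracy is
    well below 1e-6 over the practical (k, df) range.  Vectorized over
    ``q``; infinite df collapses to the plain normal-range tail.
    """
    if k < 2:
        raise ValueError("studentized range needs k >= 2 groups")
    if not df >= 1:
        raise ValueError("df must be >= 1")
    q_arr = np.atleast_1d(np.asarray(q, float))
    out = np.zeros_like(q_arr)
    finite = np.isfinite(q_arr)
    out[~finite & (q_arr < 0)] = 1.0  # -inf: sf = 1; +inf: sf = 0
    rng_cdf = _range_cdf_factory(k)
    qs = np.clip(q_arr[finite], 0.0, None)  # range is non-negative: sf(q<0) = 1
    if np.isinf(df):
        vals = 1.0 - rng_cdf(qs)
    else:
        chi = stats.chi(df, scale=1.0 / np.sqrt(df))
        lo, hi = chi.ppf(1e-11), chi.isf(1e-11)
        xs, wts = leggauss(_S_NODES)
        s = 0.5 * (hi - lo) * xs + 0.5 * (hi + lo)
        ws = 0.5 * (hi - lo) * wts * chi.pdf(s)
        vals = np.empty(qs.size)
        for start in range(0, qs.size, _CHUNK):
            block = qs[start : start + _CHUNK]
            vals[start : start + _CHUNK] = 1.0 - rng_cdf(block[:, None] * s) @ ws
    out[finite] = np.clip(vals, 0.0, 1.0)
    if np.isscalar(q) or np.asarray(q).ndim == 0:
        return float(out[0])
    return out


def tukey_pairwise_p(
    means: Sequence[float],
    sizes: Sequence[int],
    msw: float,
    df: float,
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """Tukey HSD p-value for every unordered pair of group means.

    ``msw`` is the pooled within-group mean square with ``df`` degrees of
    freedom.  For groups a, b the statistic is
    q = |m_a - m_b| / sqrt(msw/2 * (1/n_a + 1/n_b)) (the Tukey-Kramer
    form, exact for equal sizes) referred to Q(k, df).
    """
    means = np.asarray(means, float)
    sizes = np.asarray(sizes, float)
    if means.size < 2:
        raise ValueError("need at least two groups")
    if msw <= 0:
        raise ValueError("within-group mean square must be positive")
    if labels is None:
        labels = list(range(means.size))
    k = means.size
    rows = []
    qs = []
    for i, j in itertools.combinations(range(k), 2):
        q = abs(means[i] - means[j]) / np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        rows.append((labels[i], labels[j], q))
        qs.append(q)
    p = studentized_range_sf(np.array(qs), k, df)
    return pd.DataFrame(
        {"group_a": [r[0] for r in rows], "group_b": [r[1] for r in rows],
         "q": [r[2] for r in rows], "p": np.atleast_1d(p)}
    )


# ---------------------------------------------------------------------------
# fold change


def fold_change(group_means: Mapping, pair: tuple) -> float:
    """Linear fold change mean(later)/mean(earlier) for a time-point pair.

    Values above 1 denote induction, below 1 repression.
    """
    a, b = pair
    ma, mb = float(group_means[a]), float(group_means[b])
    if ma <= 0 or mb <= 0:
        raise ValueError("fold change requires positive group means")
    return mb / ma


# ---------------------------------------------------------------------------
# the DEG-calling model


def _col(prefix: str, a: float, b: float) -> str:
    return f"{prefix}_{format_timepoint(a)}h_{format_timepoint(b)}h"


@dataclass
class DEGResults:
    """Results of a fitted time-course DE analysis.

    ``table`` holds one row per gene: ANOVA F, raw and BH-adjusted p, the
    BH-gate flag, and per time-point pair the Tukey p, its within-gene
    Bonferroni correction, the linear fold change and the direction call
    ('induced'/'repressed'/'none'; 'not_tested' for genes failing the BH
    gate, whose post-hoc p columns are left missing).
    """

    table: pd.DataFrame
    pairs: list[tuple[float, float]]
    time_points: list[float]
    control: float
    alpha: float
    alpha_pair: float

    @property
    def control_pairs(self) -> list[tuple[float, float]]:
        return [p for p in self.pairs if p[0] == self.control]

    def direction(self, pair: tuple[float, float]) -> pd.Series:
        return self.table[_col("direction", *pair)]

    def fold_changes(self, pair: tuple[float, float]) -> pd.Series:
        return self.table[_col("fc", *pair)]

    def deg_mask(self, pair: tuple[float, float]) -> pd.Series:
        """Genes called differentially expressed for this pair (directional)."""
        return self.direction(pair).isin([INDUCED, REPRESSED])

    def deg_genes(self, pair: tuple[float, float], direction: str | None = None) -> set[str]:
        d = self.direction(pair)
        mask = d.isin([INDUCED, REPRESSED]) if direction is None else d == direction
        return set(self.table.index[mask])

    def any_deg_genes(self) -> set[str]:
        """Genes called DEG for at least one control-vs-t comparison."""
        out: set[str] = set()
        for pair in self.control_pairs:
            out |= self.deg_genes(pair)
        return out

    def classify_persistence(self) -> pd.DataFrame:
        return classify_persistence(self, self.control)

    def summarize_comparisons(self, two_fold_threshold: float = 2.0) -> pd.DataFrame:
        return summarize_comparisons(self, two_fold_threshold)

    def summary(self) -> str:
        lines = [
            f"Time-course DE analysis: {len(self.table)} genes, "
            f"time points {[format_timepoint(t) for t in self.time_points]} h, "
            f"control {format_timepoint(self.control)} h",
            f"BH gate alpha={self.alpha}: {int(self.table['tested'].sum())} genes entered post-hoc testing",
            f"DEGs in any control comparison: {len(self.any_deg_genes())}",
            "",
            self.summarize_comparisons().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_deg_counts(self, ax=None):
        """Bar plot of induced/repressed DEG counts per control comparison."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels, ind, rep = [], [], []
        for pair in self.control_pairs:
            labels.append(pair_label(*pair))
            d = self.direction(pair)
            ind.append(int((d == INDUCED).sum()))
            rep.append(int((d == REPRESSED).sum()))
        x = np.arange(len(labels))
        ax.bar(x - 0.2, ind, width=0.4, label="induced")
        ax.bar(x + 0.2, rep, width=0.4, label="repressed")
        ax.set_xticks(x, labels)
        ax.set_ylabel("DEGs")
        ax.legend()
        return ax

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


class ColdTimecourseDE:
    """Per-gene ANOVA + BH + Tukey HSD model for a time-series dataset.

    Parameters
    ----------
    dataset
        ``ExpressionDataset`` with >= 2 time points and >= 2 replicates per
        time point.
    alpha
        FDR level of the gene-level BH gate.
    alpha_pair
        Level for the within-gene Bonferroni-corrected Tukey tests.
    normalize
        Apply per-sample median normalization before testing.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        alpha: float = 0.05,
        alpha_pair: float = 0.05,
        normalize: bool = True,
    ) -> None:
        self.dataset = dataset
        self.alpha = float(alpha)
        self.alpha_pair = float(alpha_pair)
        self.normalize = bool(normalize)
        groups = dataset.groups()
        if len(groups) < 2:
            raise ValueError("need at least two time points")
        for t, samples in groups.items():
            if len(samples) < 2:
                raise ValueError(f"time point {t} has fewer than two replicates")

    def fit(self) -> DEGResults:
        ds = self.dataset
        matrix = median_normalize(ds.matrix) if self.normalize else ds.matrix
        tps = ds.time_points
        k = len(tps)
        group_index = ds.group_index()
        X = matrix.to_numpy(float)
        n_obs = X.shape[1]
        df_w = n_obs - k
        sizes = np.bincount(group_index, minlength=k).astype(float)

        F, p, gmeans, msw = _anova_matrix(X, group_index, k)
        p_bh = bh_adjust(p)
        tested = p_bh < self.alpha

        pairs = list(itertools.combinations(tps, 2))
        n_pairs = len(pairs)

        table = pd.DataFrame(index=matrix.index)
        table["anova_F"] = F
        table["anova_p"] = p
        table["anova_p_bh"] = p_bh
        table["tested"] = tested

        # fold changes for all genes / pairs
        fc = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for pi, (a, b) in enumerate(pairs):
                ia, ib = tps.index(a), tps.index(b)
                ratio = gmeans[:, ib] / gmeans[:, ia]
                ratio[~np.isfinite(ratio)] = np.nan
                fc[(a, b)] = ratio

        # Tukey post-hoc only for genes passing the BH gate
        idx_tested = np.flatnonzero(tested)
        qmat = np.full((len(idx_tested), n_pairs), np.nan)
        if idx_tested.size:
            msw_t = msw[idx_tested]
            for pi, (a, b) in enumerate(pairs):
                ia, ib = tps.index(a), tps.index(b)
                diff = np.abs(gmeans[idx_tested, ia] - gmeans[idx_tested, ib])
                denom = np.sqrt(msw_t / 2.0 * (1.0 / sizes[ia] + 1.0 / sizes[ib]))
                with np.errstate(divide="ignore", invalid="ignore"):
                    qmat[:, pi] = np.where(denom > 0, diff / denom,
                                           np.where(diff > 0, np.inf, 0.0))
            pmat = studentized_range_sf(qmat.ravel(), k, df_w).reshape(qmat.shape)
        else:
            pmat = qmat

        for pi, (a, b) in enumerate(pairs):
            p_col = np.full(len(table), np.nan)
            p_col[idx_tested] = pmat[:, pi]
            bonf = np.minimum(p_col * n_pairs, 1.0)
            direction = np.full(len(table), NOT_TESTED, dtype=object)
            sig = np.zeros(len(table), bool)
            sig[idx_tested] = bonf[idx_tested] < self.alpha_pair
            ratio = fc[(a, b)]
            direction[idx_tested] = NONE
            direction[sig & (ratio > 1)] = INDUCED
            direction[sig & (ratio < 1)] = REPRESSED
            table[_col("tukey_p", a, b)] = p_col
            table[_col("tukey_p_bonf", a, b)] = bonf
            table[_col("fc", a, b)] = ratio
            table[_col("direction", a, b)] = direction

        return DEGResults(
            table=table,
            pairs=pairs,
            time_points=tps,
            control=float(tps[0]),
            alpha=self.alpha,
            alpha_pair=self.alpha_pair,
        )


def call_degs(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    alpha_pair: float = 0.05,
    normalize: bool = True,
) -> DEGResults:
    """Run the full DEG-calling pipeline (normalize -> ANOVA -> BH -> Tukey)."""
    return ColdTimecourseDE(dataset, alpha=alpha, alpha_pair=alpha_pair, normalize=normalize).fit()


# ---------------------------------------------------------------------------
# downstream summaries


def classify_persistence(results: DEGResults, control: float | None = None) -> pd.DataFrame:
    """Flag genes induced (repressed) in every control-vs-t comparison.

    Returns a DataFrame with boolean columns ``persistent_induced`` and
    ``persistent_repressed``.
    """
    control = results.control if control is None else float(control)
    pairs = [p for p in results.pairs if p[0] == control]
    expected = [t for t in results.time_points if t != control]
    if sorted(p[1] for p in pairs) != sorted(expected):
        raise ValueError("control-vs-t comparison missing for some time point")
    ind = np.ones(len(results.table), bool)
    rep = np.ones(len(results.table), bool)
    for pair in pairs:
        d = results.direction(pair)
        ind &= (d == INDUCED).to_numpy()
        rep &= (d == REPRESSED).to_numpy()
    return pd.DataFrame(
        {"persistent_induced": ind, "persistent_repressed": rep}, index=results.table.index
    )


def summarize_comparisons(results: DEGResults, two_fold_threshold: float = 2.0) -> pd.DataFrame:
    """Per-pair DEG counts and fold-change ranges (one row per comparison).

    DEGs are the directional calls, so ``n_induced + n_repressed == n_deg``
    holds for every pair.  The two-fold columns count DEGs with fold change
    >= threshold or <= 1/threshold; fold-change statistics are taken over
    the pair's DEGs and left missing when the pair has none.
    """
    thr = float(two_fold_threshold)
    rows = []
    for pair in results.pairs:
        d = results.direction(pair)
        fc = results.fold_changes(pair)
        ind = d == INDUCED
        rep = d == REPRESSED
        deg = ind | rep
        big = deg & ((fc >= thr) | (fc <= 1.0 / thr))
        sel = fc[deg]
        rows.append(
            {
                "pair": pair_label(*pair),
                "n_deg": int(deg.sum()),
                "n_induced": int(ind.sum()),
                "n_repressed": int(rep.sum()),
                "n_deg_2fold": int(big.sum()),
                "n_2fold_induced": int((big & ind).sum()),
                "n_2fold_repressed": int((big & rep).sum()),
                "fc_min": float(sel.min()) if len(sel) else np.nan,
                "fc_max": float(sel.max()) if len(sel) else np.nan,
                "fc_mean": float(sel.mean()) if len(sel) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def read_deg_table(
    path: str | Path, alpha: float = 0.05, alpha_pair: float = 0.05
) -> DEGResults:
    """Reload a DEG table written by ``DEGResults.to_tsv``."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    pairs = []
    for col in table.columns:
        if col.startswith("fc_"):
            a, b = col[3:].split("_")
            pairs.append((float(a.rstrip("h")), float(b.rstrip("h"))))
    tps = sorted({t for p in pairs for t in p})
    return DEGResults(
        table=table,
        pairs=pairs,
        time_points=tps,
        control=float(tps[0]),
        alpha=alpha,
        alpha_pair=alpha_pair,
    )
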