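"""GLM contrasts of TAP-coding DEG fold changes.

Responses are log2 fold changes of the called DEG comparisons (control vs
t) of TAP-coding genes; the log scale symmetrizes induction and repression
so the sign of a mean encodes direction.  Fits are Gaussian-identity GLMs
(ordinary least squares) with Wald t tests on the residual degrees of
freedom; an intercept-only fit of one class's responses is exactly a
one-sample t-test of its mean log2 fold change.

Observations are gene x comparison responses treated as independent (no
gene-level random effect); summaries carry that caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .dataset import format_timepoint
from .degcall import DEGResults
from .go_classes import DEVELOPMENTAL, STIMULUS_STRESS

__all__ = [
    "GLMFit",
    "FoldChangeGLM",
    "fit_glm_gaussian",
    "tap_fold_change_responses",
    "test_global_class_effect",
    "test_timepoint_class_effect",
    "test_family_trend",
    "INDEPENDENCE_CAVEAT",
]

INDEPENDENCE_CAVEAT = (
    "note: gene x comparison responses are treated as independent observations"
)


@dataclass
class GLMFit:
    """Coefficients and Wald tests of one Gaussian-identity GLM."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    nobs: int
    perfect_fit: bool = False
    description: str = ""

    @property
    def estimate(self) -> float:
        """First coefficient — the mean response for intercept-only fits."""
        return float(self.params.iloc[0])

    @property
    def p(self) -> float:
        return float(self.pvalues.iloc[0])

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats

        half = stats.t.ppf(0.5 + level / 2.0, self.df_resid) * self.bse
        return pd.DataFrame({"lower": self.params - half, "upper": self.params + half})

    def summary(self) -> str:
        frame = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )
        head = self.description or "Gaussian-identity GLM"
        tail = " [perfect fit: p-values at the machine floor]" if self.perfect_fit else ""
        return (
            f"{head} (n={self.nobs}, df_resid={self.df_resid}){tail}\n"
            f"{frame.to_string()}\n{INDEPENDENCE_CAVEAT}"
        )


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        collinear = [names[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {collinear}")


def fit_glm_gaussian(
    response,
    design,
    names: list[str] | None = None,
    description: str = "",
) -> GLMFit:
    """Fit a Gaussian-identity GLM (= least squares) with Wald t tests.

    Raises on rank-deficient designs, naming the collinear columns.  A
    perfect fit (zero residual) is flagged and its p-values reported as 0,
    i.e. below any representable significance level.
    """
    y = np.asarray(response, float)
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = (
            list(design.columns)
            if isinstance(design, pd.DataFrame)
            else [f"x{i}" for i in range(X.shape[1])]
        )
    _check_design(X, names)
    fit = sm.OLS(y, X).fit()
    perfect = float(fit.ssr) <= 1e-12 * max(1.0, float(np.dot(y, y)))
    pvals = np.zeros_like(fit.params) if perfect else np.asarray(fit.pvalues)
    return GLMFit(
        params=pd.Series(np.asarray(fit.params), index=names),
        bse=pd.Series(np.asarray(fit.bse), index=names),
        tvalues=pd.Series(np.asarray(fit.tvalues), index=names),
        pvalues=pd.Series(pvals, index=names),
        df_resid=int(fit.df_resid),
        nobs=int(fit.nobs),
        perfect_fit=perfect,
        description=description,
    )


class FoldChangeGLM:
    """statsmodels-style model object: ``FoldChangeGLM(y, X).fit() -> GLMFit``.

    With ``design=None`` an intercept-only model tests whether the mean
    response differs from zero (a one-sample t-test).
    """

    def __init__(self, response, design=None, names=None, description: str = "") -> None:
        self.response = np.asarray(response, float)
        if design is None:
            design = np.ones((self.response.size, 1))
            names = names or ["intercept"]
        self.design = design
        self.names = names
        self.description = description

    def fit(self) -> GLMFit:
        return fit_glm_gaussian(self.response, self.design, self.names, self.description)


# ---------------------------------------------------------------------------
# response assembly and the class/family contrasts


def tap_fold_change_responses(
    results: DEGResults,
    annotation: pd.DataFrame,
    classification=None,
) -> pd.DataFrame:
    """Collect log2 fold changes of TAP-coding DEGs per control comparison.

    One row per (gene, control-vs-t comparison) where the gene carries a
    TAP family label and was called a DEG for that pair.  If a fitted
    ``TAPClassificationResults`` is supplied, each response inherits its
    family's specialization flag.
    """
    flag_of_family = {}
    if classification is not None:
        flag_of_family = classification.table["flag"].to_dict()
    families = annotation["tap_family"]
    rows = []
    for pair in results.control_pairs:
        mask = results.deg_mask(pair)
        fc = results.fold_changes(pair)
        for gene in results.table.index[mask]:
            fam = families.get(gene)
            if fam is None or (isinstance(fam, float) and np.isnan(fam)):
                continue
            rows.append(
                {
                    "gene_id": gene,
                    "time_point_h": pair[1],
                    "log2_fc": float(np.log2(fc[gene])),
                    "tap_family": fam,
                    "flag": flag_of_family.get(fam),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "time_point_h", "log2_fc", "tap_family", "flag"])


def _mean_fit(values: np.ndarray, description: str) -> GLMFit:
    return FoldChangeGLM(values, description=description).fit()


def test_global_class_effect(
    responses: pd.DataFrame,
    classes: tuple[str, ...] = (STIMULUS_STRESS, DEVELOPMENTAL),
    min_obs: int = 3,
) -> dict[str, GLMFit]:
    """Test, per specialization class, whether mean log2 fold change differs from 0.

    Responses pool all control-vs-t comparisons; a positive estimate means
    induction, a negative one repression.  Classes with fewer than
    ``min_obs`` responses are skipped with a warning.
    """
    fits: dict[str, GLMFit] = {}
    for cls in classes:
        vals = responses.loc[responses["flag"] == cls, "log2_fc"].to_numpy()
        if vals.size < min_obs:
            warnings.warn(f"class {cls!r}: only {vals.size} responses, skipped")
            continue
        fits[cls] = _mean_fit(vals, f"global mean log2 fold change, class {cls}")
    return fits


def test_timepoint_class_effect(
    responses: pd.DataFrame,
    classes: tuple[str, ...] = (STIMULUS_STRESS, DEVELOPMENTAL),
    min_obs: int = 3,
) -> tuple[pd.DataFrame, dict[tuple[float, str], GLMFit]]:
    """Per-time-point version of the class contrast.

    Returns a tidy table (time point, class, n, estimate, se, t, p) and the
    underlying fits; (time point, class) cells with fewer than ``min_obs``
    responses are skipped with a warning.
    """
    fits: dict[tuple[float, str], GLMFit] = {}
    rows = []
    for t in sorted(responses["time_point_h"].unique()):
        for cls in classes:
            sel = responses[(responses["time_point_h"] == t) & (responses["flag"] == cls)]
            vals = sel["log2_fc"].to_numpy()
            if vals.size < min_obs:
                warnings.warn(
                    f"time point {format_timepoint(t)} h, class {cls!r}: "
                    f"only {vals.size} responses, skipped"
                )
                continue
            fit = _mean_fit(
                vals, f"mean log2 fold change at {format_timepoint(t)} h, class {cls}"
            )
            fits[(float(t), cls)] = fit
            rows.append(
                {
                    "time_point_h": float(t),
                    "class": cls,
                    "n": fit.nobs,
                    "estimate": fit.estimate,
                    "se": float(fit.bse.iloc[0]),
                    "t": float(fit.tvalues.iloc[0]),
                    "p": fit.p,
                }
            )
    return pd.DataFrame(rows), fits


def test_family_trend(
    responses: pd.DataFrame,
    family: str,
    scope: str | float = "global",
    min_obs: int = 3,
) -> GLMFit | None:
    """Test one family's mean log2 fold change against 0.

    ``scope`` is ``'global'`` (pool all comparisons) or a time point in
    hours.  Returns ``None`` (with a warning) below ``min_obs`` responses.
    """
    sel = responses[responses["tap_family"] == family]
    label = "global"
    if scope != "global":
        sel = sel[sel["time_point_h"] == float(scope)]
        label = f"{format_timepoint(float(scope))} h"
    vals = sel["log2_fc"].to_numpy()
    if vals.size < min_obs:
        warnings.warn(f"family {family!r} ({label}): only {vals.size} responses, skipped")
        return None
    return _mean_fit(vals, f"mean log2 fold change of family {family} ({label})")
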