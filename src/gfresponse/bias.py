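"""Pathway-bias machinery and statistical panels.

The pERK and pAKT readouts live on different assay scales.  To compare them,
the pAKT fold-change distribution is linearly rescaled by a factor alpha
chosen to minimise the two-sample Cramér–von Mises distance to the pERK
fold-change distribution (grid search with one refinement pass; the CvM
objective is piecewise constant in alpha, so derivative-based optimisation
is inappropriate).  The pathway bias of a (cell line, ligand) pair is then
the arctangent of the scaled pAKT to pERK fold-change ratio, in degrees:
45° means balanced pathway activation, smaller angles ERK bias, larger
angles AKT bias.

The module also provides the panel statistics used to relate responses to
basal receptor state: Pearson/Spearman correlation panels between response
and basal predictors, two-sided Wilcoxon rank-sum comparisons between
subtype groups, and responder-versus-non-responder enrichment summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import HIGH_DOSE, TARGETS
from .errors import ValidationError
from .metrics import fold_columns


# -- Cramér–von Mises -------------------------------------------------------

def cvm_distance(sample_a, sample_b) -> float:
    """Two-sample Cramér–von Mises distance.

    Mean over the pooled sample of the squared difference between the two
    empirical distribution functions, ``(1/(n+m)) * sum (F_a - F_b)^2``.
    This is the standard rank-based two-sample discrepancy normalised so
    that it vanishes as the two empirical distributions converge (for fixed
    sample sizes it is proportional to the classical statistic, so argmin
    uses are unaffected).  Zero iff the empirical distributions coincide;
    invariant under any common strictly increasing transform.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValidationError("cvm_distance requires two nonempty samples")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / n
    fb = np.searchsorted(b, pooled, side="right") / m
    return float(np.sum((fa - fb) ** 2) / (n + m))


def fit_pathway_scale(pakt_fcs, perk_fcs, grid=None, refine: bool = True) -> float:
    """Scale factor alpha minimising ``cvm_distance(alpha*pakt, perk)``.

    Coarse log-spaced grid (default 0.1–10, 121 points) with one refinement
    pass around the coarse minimum.  Deterministic; a warning is issued if
    the optimum sits on the grid boundary.
    """
    pakt = np.asarray(pakt_fcs, dtype=float)
    perk = np.asarray(perk_fcs, dtype=float)
    if pakt.size == 0 or perk.size == 0:
        raise ValidationError("fit_pathway_scale requires two nonempty samples")
    if grid is None:
        grid = np.geomspace(0.1, 10.0, 121)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("scale grid must be nonempty")
    if (grid <= 0).any() or not np.isfinite(grid).all():
        raise ValidationError("scale grid must be positive and finite")

    def _argmin(g):
        d = np.array([cvm_distance(alpha * pakt, perk) for alpha in g])
        return int(np.argmin(d))

    i = _argmin(grid)
    if i in (0, len(grid) - 1):
        warnings.warn("pathway scale optimum lies on the grid boundary",
                      RuntimeWarning, stacklevel=2)
    if refine and len(grid) > 1:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        fine = np.geomspace(lo, hi, 41)
        return float(fine[_argmin(fine)])
    return float(grid[i])


class PathwayScaler(TransformerMixin, BaseEstimator):
    """Estimator wrapper around :func:`fit_pathway_scale`.

    ``fit(pakt_fcs, perk_fcs)`` learns ``alpha_``; ``transform`` rescales
    pAKT fold-changes onto the pERK scale.
    """

    def __init__(self, grid=None, refine: bool = True):
        self.grid = grid
        self.refine = refine

    def fit(self, X, y=None):
        if y is None:
            raise ValidationError("PathwayScaler.fit needs the pERK sample as y")
        self.alpha_ = fit_pathway_scale(X, y, grid=self.grid, refine=self.refine)
        self.distance_ = cvm_distance(self.alpha_ * np.asarray(X, dtype=float),
                                      np.asarray(y, dtype=float))
        return self

    def transform(self, X):
        return self.alpha_ * np.asarray(X, dtype=float)


def pathway_bias(perk_fc, pakt_fc, alpha: float = 1.0):
    """Bias angle in degrees: ``atan2(alpha*pakt_fc, perk_fc)``.

    Inputs are nonnegative response magnitudes on a common (scaled) footing;
    45° is balanced, 0° pure ERK, 90° pure AKT.  Returns NaN where both
    responses are zero.  Vectorised.
    """
    perk = np.asarray(perk_fc, dtype=float)
    pakt = np.asarray(pakt_fc, dtype=float)
    angle = np.degrees(np.arctan2(alpha * pakt, perk))
    angle = np.where((perk == 0) & (pakt == 0), np.nan, angle)
    if angle.ndim == 0:
        return float(angle)
    return angle


def bias_records(responses: pd.DataFrame, alpha: float, dose: float = HIGH_DOSE,
                 bias_scale: str = "fold") -> pd.DataFrame:
    """Per-(cell line, ligand) scaled fold-changes and bias angle at one dose.

    ``bias_scale="fold"`` takes the ratio on linear max fold-changes;
    ``"log_fold"`` on log10 fold-changes.
    """
    sub = responses[responses["dose"] == dose]
    wide = sub.pivot_table(index=["cell_line", "ligand"], columns="target",
                           values="max_fold_change", aggfunc="first")
    sig = sub.pivot_table(index=["cell_line", "ligand"], columns="target",
                          values="significant", aggfunc="first")
    wide = wide.dropna(subset=list(TARGETS)).reset_index()
    sig = sig.reset_index()
    out = wide.merge(sig, on=["cell_line", "ligand"], suffixes=("", "_sig"))
    if bias_scale == "fold":
        perk = 10.0 ** out["pERK"].to_numpy()
        pakt = 10.0 ** out["pAKT"].to_numpy()
    else:
        perk = np.maximum(out["pERK"].to_numpy(), 0.0)
        pakt = np.maximum(out["pAKT"].to_numpy(), 0.0)
    rec = pd.DataFrame({
        "cell_line": out["cell_line"], "ligand": out["ligand"],
        "perk_fc": perk, "pakt_fc": pakt,
        "perk_significant": out["pERK_sig"].astype(bool),
        "pakt_significant": out["pAKT_sig"].astype(bool),
        "alpha": alpha,
        "bias_angle": pathway_bias(perk, pakt, alpha),
    })
    return rec


# -- correlation panels -----------------------------------------------------

def correlate_panel(responses: pd.DataFrame, basal: pd.DataFrame,
                    method: str = "pearson", response_value: str = "fold",
                    dose: float = HIGH_DOSE, ligands=None, targets=None,
                    predictors=None, min_n: int = 3, adjust: bool = False,
                    alpha_level: float = 0.05) -> pd.DataFrame:
    """Correlate responses with basal predictors across cell lines.

    One row per (target, ligand, predictor analyte, predictor kind):
    coefficient, two-sided p-value, n, significance flag at p < 0.05, and a
    ``missing`` flag for degenerate entries (constant predictor/response or
    n < ``min_n``).  ``response_value`` is "fold" (max log10 fold-change) or
    "absolute" (max post-stimulation log10 level).  ``adjust=True`` applies a
    Benjamini–Hochberg correction across the panel.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    sub = responses[responses["dose"] == dose]
    if response_value == "fold":
        resp = sub.set_index(["cell_line", "ligand", "target"])["max_fold_change"]
    elif response_value == "absolute":
        level_cols = [c.replace("fold_t", "level_t") for c in fold_columns(responses)]
        resp = sub.set_index(["cell_line", "ligand", "target"])[level_cols].max(axis=1)
    else:
        raise ValidationError("response_value must be 'fold' or 'absolute'")
    resp = resp.rename("response").reset_index()
    if ligands is not None:
        resp = resp[resp["ligand"].isin(ligands)]
    if targets is not None:
        resp = resp[resp["target"].isin(targets)]

    preds = basal[["cell_line", "analyte", "kind", "value"]]
    if predictors is not None:
        wanted = set(map(tuple, predictors))
        preds = preds[[t in wanted for t in zip(preds["analyte"], preds["kind"])]]

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for (ligand, target), rgrp in resp.groupby(["ligand", "target"]):
        for (analyte, kind), pgrp in preds.groupby(["analyte", "kind"]):
            merged = rgrp.merge(pgrp, on="cell_line").dropna(subset=["response", "value"])
            n = len(merged)
            row = {"target": target, "ligand": ligand, "dose": dose,
                   "response_value": response_value, "analyte": analyte,
                   "kind": kind, "method": method, "n": n,
                   "coefficient": np.nan, "p_value": np.nan,
                   "missing": True, "significant": False}
            x = merged["value"].to_numpy()
            y = merged["response"].to_numpy()
            if n >= min_n and np.ptp(x) > 0 and np.ptp(y) > 0:
                res = corr_fn(x, y)
                row.update(coefficient=float(res.statistic), p_value=float(res.pvalue),
                           missing=False)
            rows.append(row)
    panel = pd.DataFrame(rows)
    if adjust and panel["p_value"].notna().any():
        ok = panel["p_value"].notna()
        panel.loc[ok, "p_value"] = stats.false_discovery_control(
            panel.loc[ok, "p_value"].to_numpy())
    panel["significant"] = panel["p_value"] < alpha_level
    return panel


# -- group comparisons ------------------------------------------------------

def compare_groups(values_a, values_b, exact_max_n: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("compare_groups requires two nonempty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class EnrichmentResult:
    """Responder-vs-non-responder comparison of basal levels."""

    p_value: float
    n_responders: int
    n_nonresponders: int
    responder_median: float
    nonresponder_median: float
    responder_iqr: tuple[float, float]
    nonresponder_iqr: tuple[float, float]
    undefined: bool = False
    low_power: bool = False


def responder_enrichment(sig_calls, levels) -> EnrichmentResult:
    """Rank-sum comparison of basal levels between responder and
    non-responder cell lines, with per-group median/IQR summaries.

    With an empty group the comparison is undefined and flagged; a group of
    size 1 is computed but flagged low-power.
    """
    sig = np.asarray(sig_calls, dtype=bool)
    lev = np.asarray(levels, dtype=float)
    if sig.shape != lev.shape:
        raise ValidationError("sig_calls and levels must align")
    resp, nonresp = lev[sig], lev[~sig]

    def _summary(v):
        if v.size == 0:
            return np.nan, (np.nan, np.nan)
        return float(np.median(v)), tuple(np.percentile(v, [25, 75]))

    rm, riqr = _summary(resp)
    nm, niqr = _summary(nonresp)
    if resp.size == 0 or nonresp.size == 0:
        return EnrichmentResult(np.nan, resp.size, nonresp.size, rm, nm, riqr, niqr,
                                undefined=True)
    p = compare_groups(resp, nonresp)
    return EnrichmentResult(p, resp.size, nonresp.size, rm, nm, riqr, niqr,
                            low_power=min(resp.size, nonresp.size) < 2)
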