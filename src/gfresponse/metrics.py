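"""Per-condition response quantities.

Replicates are averaged in the log10 domain.  For each (cell line, target)
the time-0 control replicates define a control model (mean and sample SD of
the log10 signal); a condition's response is the trajectory of log10
fold-changes (averaged level minus control mean) at the post-stimulation
times, summarised by its maximum.

A response is called significant when its maximum averaged level reaches
``control_mean + m * control_sd`` (m = 2 by default) *and* exceeds the
control mean.  The second clause only matters in the degenerate case
control_sd = 0, where it keeps an exactly-flat trajectory non-significant
while any strictly positive excursion remains significant.  With the
conventional control SD the rule corresponds to calling fold-changes below
roughly 1.2-fold non-significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import CONTROL_LIGAND
from .errors import ValidationError
from .io import ResponseCube

RESPONSE_KEY = ["cell_line", "ligand", "dose", "target"]


def average_replicates_log(values) -> float:
    """Arithmetic mean of log10 measurements (geometric mean in linear units)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot average an empty replicate collection")
    if not np.isfinite(arr).all():
        raise ValidationError("replicate values must be finite")
    return float(arr.mean())


def fit_control_model(cube: ResponseCube, min_replicates: int = 2) -> pd.DataFrame:
    """Per-(cell line, target) mean and sample SD of the time-0 control log10 values."""
    ctrl = cube.controls
    grouped = ctrl.groupby(["cell_line", "target"])["value"]
    counts = grouped.size()
    thin = counts[counts < min_replicates]
    if len(thin):
        raise ValidationError(
            f"control group(s) with fewer than {min_replicates} replicates: "
            f"{list(thin.index)[:5]}")
    model = grouped.agg(control_mean="mean", control_sd=lambda v: v.std(ddof=1)).reset_index()
    return model


def call_significance(max_level, control_mean, control_sd, sd_multiplier: float = 2.0):
    """Significance call(s); vectorised over array-like inputs.

    True iff ``max_level >= control_mean + sd_multiplier * control_sd`` and
    ``max_level > control_mean``.
    """
    max_level = np.asarray(max_level, dtype=float)
    control_mean = np.asarray(control_mean, dtype=float)
    control_sd = np.asarray(control_sd, dtype=float)
    sig = (max_level >= control_mean + sd_multiplier * control_sd) & (max_level > control_mean)
    if sig.ndim == 0:
        return bool(sig)
    return sig


def compute_fold_changes(cube: ResponseCube, model: pd.DataFrame | None = None,
                         sd_multiplier: float = 2.0) -> pd.DataFrame:
    """Condition-level response table.

    One row per (cell line, ligand, dose, target) with replicate-averaged
    log10 levels and fold-changes per post-stimulation time (columns
    ``level_t{t}`` / ``fold_t{t}``), the control mean (``basal``) and SD, the
    maximum fold-change across times (log10 units) and the significance call.
    """
    if model is None:
        model = fit_control_model(cube)
    stim = cube.stimulated
    post_times = sorted(stim["time"].unique())
    levels = (stim.groupby(RESPONSE_KEY + ["time"])["value"].mean()
              .unstack("time").reset_index())
    levels.columns.name = None
    missing = levels[post_times].isna()
    if missing.to_numpy().any():
        bad = levels.loc[missing.any(axis=1), RESPONSE_KEY].head()
        raise ValidationError(f"conditions missing time points: {bad.to_dict('records')}")
    out = levels.merge(model, on=["cell_line", "target"], how="left", validate="m:1")
    if out["control_mean"].isna().any():
        bad = out.loc[out["control_mean"].isna(), ["cell_line", "target"]].drop_duplicates()
        raise ValidationError(f"no control model for: {bad.to_dict('records')}")
    for t in post_times:
        out[f"fold_t{t}"] = out[t] - out["control_mean"]
    level_cols = {t: f"level_t{t}" for t in post_times}
    out = out.rename(columns=level_cols)
    fold_cols = [f"fold_t{t}" for t in post_times]
    out["max_fold_change"] = out[fold_cols].max(axis=1)
    max_level = out[[level_cols[t] for t in post_times]].max(axis=1)
    out["significant"] = call_significance(max_level, out["control_mean"],
                                           out["control_sd"], sd_multiplier)
    out = out.rename(columns={"control_mean": "basal"})
    out.attrs["post_times"] = post_times
    return out.sort_values(RESPONSE_KEY, kind="mergesort").reset_index(drop=True)


def overall_max_fold(responses: pd.DataFrame) -> pd.DataFrame:
    """Max induction per (cell line, ligand, target) across all times and doses.

    Also reports whether the response is significant at either dose — the
    quantities driving ligand→target graph edges.
    """
    agg = (responses.groupby(["cell_line", "ligand", "target"])
           .agg(max_fold=("max_fold_change", "max"),
                significant=("significant", "any"))
           .reset_index())
    return agg


def fold_columns(responses: pd.DataFrame) -> list[str]:
    """Names of the per-time fold-change columns, in time order."""
    times = responses.attrs.get("post_times")
    if times is None:
        times = sorted(int(c[6:]) for c in responses.columns if c.startswith("fold_t"))
    return [f"fold_t{t}" for t in times]


class ResponseSummarizer(TransformerMixin, BaseEstimator):
    """Estimator wrapper: fit the control model on a cube, transform cubes
    into condition-level response tables.

    Parameters
    ----------
    sd_multiplier : float, default=2.0
        Number of control SDs the maximum level must clear for significance.
    """

    def __init__(self, sd_multiplier: float = 2.0):
        self.sd_multiplier = sd_multiplier

    def fit(self, X: ResponseCube, y=None):
        self.control_model_ = fit_control_model(X)
        return self

    def transform(self, X: ResponseCube) -> pd.DataFrame:
        if not hasattr(self, "control_model_"):
            raise ValidationError("ResponseSummarizer is not fitted")
        return compute_fold_changes(X, self.control_model_, self.sd_multiplier)


def assemble_summary(responses: pd.DataFrame, kinetics: pd.DataFrame,
                     sensitivity: pd.DataFrame) -> pd.DataFrame:
    """Join fold-changes, per-dose kinetic labels and sensitivity classes into
    the per-(cell line, ligand, target) summary table."""
    from .constants import HIGH_DOSE, LOW_DOSE

    merged = responses.merge(
        kinetics[RESPONSE_KEY + ["label"]], on=RESPONSE_KEY, how="left")
    pieces = {}
    for dose, tag in ((LOW_DOSE, "low"), (HIGH_DOSE, "high")):
        sub = merged[merged["dose"] == dose]
        pieces[tag] = sub.set_index(["cell_line", "ligand", "target"])[
            ["max_fold_change", "significant", "label"]].rename(columns={
                "max_fold_change": f"fc_{tag}", "significant": f"sig_{tag}",
                "label": f"kinetic_{tag}"})
    out = pieces["low"].join(pieces["high"], how="outer").reset_index()
    out = out.merge(sensitivity[["cell_line", "ligand", "target", "label"]]
                    .rename(columns={"label": "sensitivity"}),
                    on=["cell_line", "ligand", "target"], how="left")
    from .io import SUMMARY_COLUMNS
    out = out.reindex(columns=SUMMARY_COLUMNS)
    return out.sort_values(["cell_line", "ligand", "target"], kind="mergesort").reset_index(drop=True)
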