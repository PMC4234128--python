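"""Tabular input/output and the validated data containers.

All tables travel as pandas DataFrames with canonical long-format schemas:

``ResponseCube.data``
    one phospho measurement per row:
    ``cell_line, ligand, dose, time, target, replicate, value`` where ``value``
    is a log10 ELISA signal, ``dose`` is ng/ml (NaN on time-0 controls) and
    ``ligand == "control"`` exactly on time-0 rows.

basal table
    ``cell_line, analyte, kind, value, below_detection`` — per-cell-line RTK
    (and ERK/AKT) expression and phosphorylation in log10 units; values below
    an analyte's detection threshold are floored to the threshold and flagged.

ligand–receptor map
    two-column edge list ``ligand, receptor``.

subtype table
    ``cell_line, subtype`` with subtype in {TNBC, HER2amp, HRpos}.

summary table
    one row per (cell line, ligand, target) with the per-dose fold-changes,
    significance flags and kinetic classes, plus the dose-sensitivity class —
    the tabular twin of a per-panel response overview.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import CONTROL_LIGAND, DOSES, KINDS, SUBTYPES, TARGETS, TIMES
from .errors import ParseError, SchemaError, ValidationError

CUBE_COLUMNS = ["cell_line", "ligand", "dose", "time", "target", "replicate", "value"]
BASAL_COLUMNS = ["cell_line", "analyte", "kind", "value", "below_detection"]
SUMMARY_COLUMNS = [
    "cell_line", "ligand", "target",
    "fc_low", "fc_high", "sig_low", "sig_high",
    "kinetic_low", "kinetic_high", "sensitivity",
]


@dataclass
class Dialect:
    """Column naming / layout of an input response table.

    ``columns`` maps canonical names to the file's column names.  ``fmt`` may
    be ``"long"`` (one measurement per row, the canonical layout) or
    ``"wide"`` with one column per time point given by ``time_columns``
    (mapping minutes to column names).
    """

    delimiter: str = ","
    fmt: str = "long"
    columns: dict = field(default_factory=dict)
    time_columns: dict | None = None

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _to_numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{what}: non-numeric '{col}' value {df[col].iloc[idx]!r} at row {idx}")
    return out


class ResponseCube:
    """Validated container for the stimulation–response measurement cube."""

    def __init__(self, data: pd.DataFrame, times: Iterable[int] = TIMES,
                 doses: Iterable[float] = DOSES, validate: bool = True):
        _require_columns(data, CUBE_COLUMNS, "response table")
        df = data.loc[:, CUBE_COLUMNS].copy()
        df["cell_line"] = df["cell_line"].astype(str)
        df["ligand"] = df["ligand"].astype(str)
        df["target"] = df["target"].astype(str)
        df["dose"] = pd.to_numeric(df["dose"], errors="coerce")
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(int)
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        self.data = df.reset_index(drop=True)
        self.times = tuple(sorted(int(t) for t in times))
        self.doses = tuple(sorted(float(d) for d in doses))
        if validate:
            self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if not np.isfinite(df["value"]).all():
            idx = int(np.flatnonzero(~np.isfinite(df["value"].to_numpy()))[0])
            raise ValidationError(f"non-finite measurement value at row {idx}")
        bad_target = ~df["target"].isin(TARGETS)
        if bad_target.any():
            raise ValidationError(
                f"unknown target(s) {sorted(df.loc[bad_target, 'target'].unique())}; "
                f"allowed: {list(TARGETS)}")
        bad_time = ~df["time"].isin(self.times)
        if bad_time.any():
            raise ValidationError(
                f"time point(s) {sorted(df.loc[bad_time, 'time'].unique())} outside {self.times}")

        is_ctrl = df["time"] == 0
        if (df.loc[is_ctrl, "ligand"] != CONTROL_LIGAND).any():
            raise ValidationError("time-0 rows must carry ligand='control'")
        if (df.loc[~is_ctrl, "ligand"] == CONTROL_LIGAND).any():
            raise ValidationError("ligand='control' rows must have time=0")
        if df.loc[is_ctrl, "dose"].notna().any():
            raise ValidationError("control rows must not carry a dose")
        stim_dose = df.loc[~is_ctrl, "dose"]
        bad_dose = stim_dose.isna() | ~stim_dose.isin(self.doses)
        if bad_dose.any():
            vals = sorted(set(stim_dose[bad_dose].fillna(float("nan")).tolist()))
            raise ValidationError(f"malformed dose(s) {vals}; stimulated rows need dose in {self.doses}")

        stim_groups = set(map(tuple, df.loc[~is_ctrl, ["cell_line", "target"]].drop_duplicates().itertuples(index=False)))
        ctrl_groups = set(map(tuple, df.loc[is_ctrl, ["cell_line", "target"]].drop_duplicates().itertuples(index=False)))
        orphans = sorted(stim_groups - ctrl_groups)
        if orphans:
            raise ValidationError(f"stimulated measurements without a time-0 control: {orphans[:5]}")

    # -- views --------------------------------------------------------------
    @property
    def controls(self) -> pd.DataFrame:
        return self.data[self.data["time"] == 0]

    @property
    def stimulated(self) -> pd.DataFrame:
        return self.data[self.data["time"] > 0]

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())

    @property
    def ligands(self) -> list[str]:
        return sorted(set(self.data["ligand"].unique()) - {CONTROL_LIGAND})

    def __len__(self) -> int:
        return len(self.data)

    def _canonical(self) -> pd.DataFrame:
        return (self.data.sort_values(CUBE_COLUMNS, kind="mergesort")
                .reset_index(drop=True))

    def equals(self, other: "ResponseCube") -> bool:
        a, b = self._canonical(), other._canonical()
        if a.shape != b.shape:
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=0, atol=1e-12)
        except AssertionError:
            return False
        return True


# -- response cube ----------------------------------------------------------

def read_response_table(path, dialect: Dialect | None = None) -> ResponseCube:
    """Read a CSV/TSV of phospho measurements into a validated :class:`ResponseCube`."""
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.fmt == "wide":
        id_canon = ["cell_line", "ligand", "dose", "target", "replicate"]
        rename = {dialect.resolve(c): c for c in id_canon}
        _require_columns(raw, rename.keys(), "response table")
        raw = raw.rename(columns=rename)
        tcols = dialect.time_columns or {t: f"t{t}" for t in TIMES}
        _require_columns(raw, tcols.values(), "response table (time columns)")
        long = raw.melt(id_vars=id_canon, value_vars=list(tcols.values()),
                        var_name="_tcol", value_name="value")
        col_to_time = {v: int(k) for k, v in tcols.items()}
        long["time"] = long["_tcol"].map(col_to_time)
        long = long.drop(columns="_tcol")
        ctrl = long["time"] == 0
        long.loc[ctrl, "ligand"] = CONTROL_LIGAND
        long.loc[ctrl, "dose"] = np.nan
        long = long.drop_duplicates(subset=CUBE_COLUMNS[:-1])
        raw = long
    else:
        rename = {dialect.resolve(c): c for c in CUBE_COLUMNS}
        _require_columns(raw, rename.keys(), "response table")
        raw = raw.rename(columns=rename)
    raw["value"] = _to_numeric(raw, "value", "response table")
    dose_num = pd.to_numeric(raw["dose"], errors="coerce")
    malformed = dose_num.isna() & raw["dose"].notna()
    if malformed.any():
        idx = int(np.flatnonzero(malformed.to_numpy())[0])
        raise ValidationError(
            f"response table: malformed dose {raw['dose'].iloc[idx]!r} at row {idx}")
    raw["dose"] = dose_num
    return ResponseCube(raw)


def write_response_table(cube: ResponseCube, path, delimiter: str = ",") -> None:
    cube.data.to_csv(path, sep=delimiter, index=False)


# -- basal profiles ---------------------------------------------------------

def read_basal_table(path, thresholds: Mapping[str, float] | None = None,
                     delimiter: str = ",") -> pd.DataFrame:
    """Read per-cell-line basal expression/phosphorylation profiles.

    ``thresholds`` (per-analyte detection thresholds, log10 units) enforces
    the flooring invariant: any row flagged ``below_detection`` must carry
    exactly its analyte's threshold value.  Without thresholds, flagged rows
    of an analyte must at least share a single common (threshold) value.
    """
    raw = pd.read_csv(path, sep=delimiter)
    _require_columns(raw, BASAL_COLUMNS, "basal table")
    df = raw.loc[:, BASAL_COLUMNS].copy()
    df["value"] = _to_numeric(df, "value", "basal table")
    df["below_detection"] = df["below_detection"].map(_parse_bool)
    bad_kind = ~df["kind"].isin(KINDS)
    if bad_kind.any():
        raise ValidationError(f"basal table: unknown kind(s) {sorted(df.loc[bad_kind, 'kind'].unique())}")
    validate_basal(df, thresholds)
    return df.reset_index(drop=True)


def validate_basal(df: pd.DataFrame, thresholds: Mapping[str, float] | None = None) -> None:
    flagged = df[df["below_detection"]]
    if thresholds is not None:
        for analyte, grp in flagged.groupby("analyte"):
            if analyte not in thresholds:
                raise ValidationError(f"basal table: no detection threshold configured for {analyte!r}")
            if not np.allclose(grp["value"], thresholds[analyte], rtol=0, atol=0):
                raise ValidationError(
                    f"basal table: below-detection rows for {analyte!r} must equal the "
                    f"threshold {thresholds[analyte]}")
    else:
        counts = flagged.groupby("analyte")["value"].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise ValidationError(
                f"basal table: below-detection rows of {list(bad.index)} carry inconsistent values")


def write_basal_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.loc[:, BASAL_COLUMNS].to_csv(path, sep=delimiter, index=False)


# -- ligand–receptor map ----------------------------------------------------

def read_ligand_receptor_map(path, delimiter: str = ",") -> dict[str, set[str]]:
    raw = pd.read_csv(path, sep=delimiter)
    _require_columns(raw, ["ligand", "receptor"], "ligand-receptor map")
    lrmap: dict[str, set[str]] = {}
    for lig, rec in raw[["ligand", "receptor"]].itertuples(index=False):
        lrmap.setdefault(str(lig), set()).add(str(rec))
    validate_lrmap(lrmap)
    return lrmap


def validate_lrmap(lrmap: Mapping[str, set[str]], analytes: Iterable[str] | None = None) -> None:
    for lig, recs in lrmap.items():
        if not recs:
            raise ValidationError(f"ligand {lig!r} has no receptor")
    if analytes is not None:
        known = set(analytes)
        unknown = {r for recs in lrmap.values() for r in recs} - known
        if unknown:
            raise ValidationError(f"receptors {sorted(unknown)} not among basal analytes")


def write_ligand_receptor_map(lrmap: Mapping[str, set[str]], path, delimiter: str = ",") -> None:
    rows = [(lig, rec) for lig in sorted(lrmap) for rec in sorted(lrmap[lig])]
    pd.DataFrame(rows, columns=["ligand", "receptor"]).to_csv(path, sep=delimiter, index=False)


# -- subtype table ----------------------------------------------------------

def read_subtype_table(path, delimiter: str = ",") -> pd.DataFrame:
    raw = pd.read_csv(path, sep=delimiter)
    _require_columns(raw, ["cell_line", "subtype"], "subtype table")
    df = raw.loc[:, ["cell_line", "subtype"]].astype(str)
    bad = ~df["subtype"].isin(SUBTYPES)
    if bad.any():
        raise ValidationError(f"unknown subtype(s) {sorted(df.loc[bad, 'subtype'].unique())}")
    if df["cell_line"].duplicated().any():
        dupes = sorted(df.loc[df['cell_line'].duplicated(), 'cell_line'].unique())
        raise ValidationError(f"cell line(s) listed more than once in subtype table: {dupes}")
    return df.reset_index(drop=True)


def write_subtype_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.loc[:, ["cell_line", "subtype"]].to_csv(path, sep=delimiter, index=False)


# -- summary table ----------------------------------------------------------

def write_summary_table(summary: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write the per-(cell line, ligand, target) response summary."""
    out = summary.reindex(columns=SUMMARY_COLUMNS)
    out.to_csv(path, sep=delimiter, index=False)


def read_summary_table(path, delimiter: str = ",") -> pd.DataFrame:
    raw = pd.read_csv(path, sep=delimiter)
    _require_columns(raw, SUMMARY_COLUMNS, "summary table")
    df = raw.loc[:, SUMMARY_COLUMNS].copy()
    for col in ("sig_low", "sig_high"):
        df[col] = df[col].map(_parse_bool, na_action="ignore")
    return df


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ParseError(f"cannot parse boolean value {x!r}")
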