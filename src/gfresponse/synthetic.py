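"""Synthetic response panels with planted ground truth.

The generator emulates the statistical structure of a growth-factor response
screen: a panel of cell lines (default 39) × ligands (default 15) stimulated
at 1 and 100 ng/ml, with duplicate pERK/pAKT log10 measurements at 10, 30
and 90 minutes plus unstimulated time-0 controls, basal RTK
expression/phosphorylation profiles with detection-threshold censoring, a
subtype table, and a ligand→receptor binding map.

Planted structure per (cell line, ligand, target):

* a responder indicator drawn with a ligand-dependent probability (broadly
  active ligands respond in nearly every line, weak ligands in few; the
  default range averages to ~60% responding combinations at pERK and ~50%
  at pAKT); responders get a kinetic class from {sustained, transient,
  late}, non-responders are "none"; the
  trajectory of log10 fold-changes at (10, 30, 90) min follows the class
  template with a single amplitude ``a``: sustained = (a, a, a),
  transient = (a, a/2, a/10), late = (a/10, a/2, a), none = (0, 0, 0);
* a dose-sensitivity class for responders: the low-dose response magnitude
  (linear fold − 1) is a fixed fraction of the high-dose one — 0.85 for
  "equal" (above the 75% rule), 0.5 for "high_greater", and 0 (no low-dose
  response) for "high_only";
* a pERK peak amplitude that depends log-linearly on the cognate receptor's
  basal expression with a positive coefficient and on basal ErbB2 with a
  negative coefficient;
* pAKT linear fold-changes drawn from the pERK fold-change distribution
  compressed by 1/alpha_true, so the pathway scale factor is recoverable.

Measurement noise is i.i.d. Gaussian in the log10 domain (multiplicative in
linear units).  The default noise SD is log10(1.2)/2, making the 2-SD
significance rule correspond to a ~1.2-fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (CONTROL_LIGAND, DOSES, HIGH_DOSE, KINETIC_CLASSES,
                        LOG10_1P2, LOW_DOSE, POST_TIMES, SUBTYPES, TARGETS)
from .errors import ConfigError
from .io import ResponseCube

#: Canonical ligand panel with cognate receptors (one receptor per ligand).
DEFAULT_LIGAND_RECEPTORS = {
    "EGF": "EGFR", "TGFA": "EGFR", "BTC": "ERBB4", "EPR": "ERBB4",
    "HRG": "ERBB3", "IGF1": "IGF1R", "IGF2": "IGF1R", "INS": "INSR",
    "FGF1": "FGFR1", "FGF2": "FGFR1", "HGF": "MET", "NGF": "NTRK1",
    "PDGFB": "PDGFRB", "SCF": "KIT", "VEGFA": "KDR",
}

#: Negative-modulator analyte measured on every line.
ERBB2 = "ERBB2"


@dataclass
class GeneratorConfig:
    """Planted parameters of the synthetic screen (log10 units throughout)."""

    sigma: float = LOG10_1P2 / 2          # replicate noise SD
    alpha_true: float = 2.386             # pAKT→pERK pathway scale factor
    n_replicates: int = 2
    #: per-ligand pERK responder probability, linearly spaced from max (first
    #: ligand, broadly active ErbB-like) to min (last ligand); the default
    #: range averages to 60% responding cell-ligand combinations.
    response_prob_max: float = 0.95
    response_prob_min: float = 0.25
    #: pAKT responder probabilities are the pERK ones times this factor
    #: (~50% of combinations respond at pAKT vs ~60% at pERK).
    pakt_response_factor: float = 50.0 / 60.0
    #: kinetic-class proportions among responders: about half sustained, the
    #: remainder split between transient and late.
    kinetic_proportions: dict = field(default_factory=lambda: {
        "sustained": 0.50, "transient": 0.25, "late": 0.25})
    sensitivity_proportions: dict = field(default_factory=lambda: {
        "equal": 0.40, "high_greater": 0.35, "high_only": 0.25})
    equal_ratio: float = 0.85             # low-dose (fold−1) fraction for "equal"
    high_greater_ratio: float = 0.50      # … for "high_greater"
    # pERK peak amplitude model: base + b_r*(receptor − r_mean) + b_h*(erbb2 − h_mean) + jitter
    # Chosen so receptor–response correlations across a 39-line panel land
    # around |r| ~ 0.65, the magnitude such screens report.  The ErbB2 term
    # acts on the deviation from the realized panel mean.
    amplitude_base: float = 1.3
    receptor_coef: float = 0.8
    erbb2_coef: float = -0.65
    amplitude_jitter: float = 0.1
    #: smallest planted responder amplitude (~2.5-fold); keeps every planted
    #: responder well above the ~1.2-fold significance scale and keeps the
    #: compressed pAKT linear folds above 1.
    min_amplitude: float = 0.4
    #: responder probability is modulated multiplicatively by the cognate
    #: receptor's and ErbB2's deviation from the panel mean: receptor-poor /
    #: ErbB2-rich lines are less likely to respond at all, mirroring the
    #: higher basal RTK levels seen among responder lines.  Multiplicative
    #: modulation keeps the responder amplitude distributions of the two
    #: targets identical, so the planted pathway scale stays recoverable
    #: from significant responses.
    response_receptor_slope: float = 0.35
    response_erbb2_slope: float = -0.15
    # basal profile model
    receptor_mean: float = 3.0
    receptor_sd: float = 0.5
    phospho_offset: float = -1.0
    phospho_sd: float = 0.3
    erbb2_mean: float = 2.5
    erbb2_sd: float = 0.4
    her2amp_shift: float = 1.0            # ErbB2 surplus of HER2-amplified lines
    basal_target_mean: float = 2.0
    basal_target_sd: float = 0.3
    detection_threshold: float = 1.2
    subtype_proportions: dict = field(default_factory=lambda: {
        "TNBC": 0.45, "HER2amp": 0.30, "HRpos": 0.25})

    def __post_init__(self):
        for name, props in (("kinetic_proportions", self.kinetic_proportions),
                            ("sensitivity_proportions", self.sensitivity_proportions),
                            ("subtype_proportions", self.subtype_proportions)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in props.values()):
                raise ConfigError(f"{name} must be nonnegative")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.alpha_true <= 0:
            raise ConfigError("alpha_true must be > 0")


@dataclass
class GroundTruth:
    """Planted truth of a generated panel.

    ``classes`` has one row per (cell_line, ligand, target) with the planted
    kinetic class, sensitivity class and per-dose peak amplitudes (log10).
    ``expected`` adds the per-dose expected calls: a trajectory is expected
    significant iff its planted amplitude is positive, and its expected
    kinetic label is the planted class when that dose responds, else "none"
    (a "high_only" pair has a genuinely flat low-dose trajectory).
    """

    classes: pd.DataFrame
    receptor_levels: pd.DataFrame     # uncensored basal values (cell_line × analyte/kind)
    alpha_true: float
    sigma: float
    seed: int
    config: GeneratorConfig

    @property
    def expected(self) -> pd.DataFrame:
        rows = []
        for dose, amp_col in ((LOW_DOSE, "amp_low"), (HIGH_DOSE, "amp_high")):
            sub = self.classes.copy()
            sub["dose"] = dose
            sub["expected_significant"] = sub[amp_col] > 0
            sub["expected_kinetic"] = np.where(sub["expected_significant"],
                                               sub["kinetic_class"], "none")
            sub["expected_amplitude"] = sub[amp_col]
            rows.append(sub[["cell_line", "ligand", "target", "dose",
                             "expected_significant", "expected_kinetic",
                             "expected_amplitude"]])
        return pd.concat(rows, ignore_index=True)


@dataclass
class PanelBundle:
    """Everything :func:`generate_panel` produces."""

    cube: ResponseCube
    basal: pd.DataFrame
    subtypes: pd.DataFrame
    lrmap: dict[str, set[str]]
    truth: GroundTruth


def _template(kinetic: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """Log10 fold-change at (10, 30, 90) min for planted classes/amplitudes."""
    shapes = {
        "sustained": (1.0, 1.0, 1.0),
        "transient": (1.0, 0.5, 0.1),
        "late": (0.1, 0.5, 1.0),
        "none": (0.0, 0.0, 0.0),
    }
    mat = np.zeros((len(kinetic), len(POST_TIMES)))
    for cls, shape in shapes.items():
        mask = kinetic == cls
        mat[mask] = amplitude[mask, None] * np.asarray(shape)
    return mat


def _low_dose_amplitude(amp_high: np.ndarray, sensitivity: np.ndarray,
                        cfg: GeneratorConfig) -> np.ndarray:
    """Planted low-dose peak: fixed fraction of the high-dose response magnitude."""
    ratio = np.select(
        [sensitivity == "equal", sensitivity == "high_greater"],
        [cfg.equal_ratio, cfg.high_greater_ratio],
        default=0.0,
    )
    return np.log10(1.0 + ratio * (10.0 ** amp_high - 1.0))


def sample_fold_changes(n: int, rng: np.random.Generator,
                        config: GeneratorConfig | None = None) -> np.ndarray:
    """Draw ``n`` linear pERK peak fold-changes from the panel's marginal
    amplitude distribution (receptor and ErbB2 effects marginalised)."""
    cfg = config or GeneratorConfig()
    receptor = rng.normal(cfg.receptor_mean, cfg.receptor_sd, n)
    her2 = rng.random(n) < cfg.subtype_proportions["HER2amp"]
    erbb2 = rng.normal(cfg.erbb2_mean, cfg.erbb2_sd, n) + cfg.her2amp_shift * her2
    erbb2_center = cfg.erbb2_mean + cfg.her2amp_shift * cfg.subtype_proportions["HER2amp"]
    amp = _amplitude(receptor, erbb2, erbb2_center, rng, cfg)
    return 10.0 ** amp


def _amplitude(receptor: np.ndarray, erbb2: np.ndarray, erbb2_center: float,
               rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    a = (cfg.amplitude_base
         + cfg.receptor_coef * (receptor - cfg.receptor_mean)
         + cfg.erbb2_coef * (erbb2 - erbb2_center)
         + rng.normal(0.0, cfg.amplitude_jitter, np.shape(receptor)))
    return np.maximum(a, cfg.min_amplitude)


def censor_at_threshold(profiles: pd.DataFrame,
                        thresholds: Mapping[str, float] | float) -> pd.DataFrame:
    """Floor basal values at their analyte's detection threshold and flag them."""
    out = profiles.copy()
    if isinstance(thresholds, Mapping):
        thr = out["analyte"].map(thresholds)
        if thr.isna().any():
            missing = sorted(out.loc[thr.isna(), "analyte"].unique())
            raise ConfigError(f"no detection threshold for analyte(s) {missing}")
        thr = thr.astype(float).to_numpy()
    else:
        thr = np.full(len(out), float(thresholds))
    below = out["value"].to_numpy() < thr
    out["value"] = np.where(below, thr, out["value"])
    out["below_detection"] = out.get("below_detection", False) | below
    return out


def generate_panel(n_cell_lines: int = 39, n_ligands: int = 15, seed: int = 0,
                   config: GeneratorConfig | None = None, **overrides) -> PanelBundle:
    """Generate a full synthetic screen with planted ground truth.

    Deterministic in ``(seed, config)``.  ``overrides`` are applied on top of
    ``config`` (e.g. ``sigma=0`` for a noiseless panel).
    """
    if n_cell_lines < 1 or n_ligands < 1:
        raise ConfigError("need at least one cell line and one ligand")
    cfg = config or GeneratorConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(seed)

    cells = [f"CL{i + 1:02d}" for i in range(n_cell_lines)]
    if n_ligands <= len(DEFAULT_LIGAND_RECEPTORS):
        ligands = list(DEFAULT_LIGAND_RECEPTORS)[:n_ligands]
        lrmap = {l: {DEFAULT_LIGAND_RECEPTORS[l]} for l in ligands}
    else:
        ligands = [f"LIG{i + 1:02d}" for i in range(n_ligands)]
        lrmap = {l: {f"{l}R"} for l in ligands}
    receptors = sorted({r for recs in lrmap.values() for r in recs})
    cognate = {l: sorted(lrmap[l])[0] for l in ligands}

    # subtypes ---------------------------------------------------------------
    subtype_names = list(cfg.subtype_proportions)
    subtype = rng.choice(subtype_names, size=n_cell_lines,
                         p=[cfg.subtype_proportions[s] for s in subtype_names])
    subtypes = pd.DataFrame({"cell_line": cells, "subtype": subtype})

    # basal profiles ---------------------------------------------------------
    expr = {r: rng.normal(cfg.receptor_mean, cfg.receptor_sd, n_cell_lines)
            for r in receptors}
    expr[ERBB2] = (rng.normal(cfg.erbb2_mean, cfg.erbb2_sd, n_cell_lines)
                   + cfg.her2amp_shift * (subtype == "HER2amp"))
    phospho = {a: v + cfg.phospho_offset + rng.normal(0, cfg.phospho_sd, n_cell_lines)
               for a, v in expr.items()}
    basal_target = {t: rng.normal(cfg.basal_target_mean, cfg.basal_target_sd, n_cell_lines)
                    for t in TARGETS}

    basal_rows = []
    for analyte in receptors + [ERBB2]:
        basal_rows.append(pd.DataFrame({
            "cell_line": cells, "analyte": analyte, "kind": "expression",
            "value": expr[analyte], "below_detection": False}))
        basal_rows.append(pd.DataFrame({
            "cell_line": cells, "analyte": analyte, "kind": "phosphorylation",
            "value": phospho[analyte], "below_detection": False}))
    for target, kinase in (("pERK", "ERK"), ("pAKT", "AKT")):
        basal_rows.append(pd.DataFrame({
            "cell_line": cells, "analyte": kinase, "kind": "expression",
            "value": rng.normal(cfg.receptor_mean, cfg.phospho_sd, n_cell_lines),
            "below_detection": False}))
        basal_rows.append(pd.DataFrame({
            "cell_line": cells, "analyte": kinase, "kind": "phosphorylation",
            "value": basal_target[target], "below_detection": False}))
    basal_raw = pd.concat(basal_rows, ignore_index=True)
    basal = censor_at_threshold(basal_raw, cfg.detection_threshold)

    # planted classes and amplitudes ----------------------------------------
    cell_idx = {c: i for i, c in enumerate(cells)}
    grid = pd.MultiIndex.from_product([cells, ligands, TARGETS],
                                      names=["cell_line", "ligand", "target"])
    classes = grid.to_frame(index=False)
    n_cond = len(classes)
    lig_prob = {l: p for l, p in zip(ligands, np.linspace(
        cfg.response_prob_max, cfg.response_prob_min, n_ligands))}
    ci0 = classes["cell_line"].map(cell_idx).to_numpy()
    rec_level0 = np.array([expr[cognate[l]][i] for l, i in zip(classes["ligand"], ci0)])
    erbb2_center = float(expr[ERBB2].mean())
    prob = classes["ligand"].map(lig_prob).to_numpy()
    prob = np.where(classes["target"] == "pAKT", prob * cfg.pakt_response_factor, prob)
    modulation = np.clip(
        1.0 + cfg.response_receptor_slope * (rec_level0 - cfg.receptor_mean)
        + cfg.response_erbb2_slope * (expr[ERBB2][ci0] - erbb2_center),
        0.05, 1.95)
    responds = rng.random(n_cond) < np.clip(prob * modulation, 0.02, 0.98)
    kin_names = [c for c in KINETIC_CLASSES if c in cfg.kinetic_proportions]
    drawn = rng.choice(kin_names, size=n_cond,
                       p=[cfg.kinetic_proportions[c] for c in kin_names])
    classes["kinetic_class"] = np.where(responds, drawn, "none")
    sens_names = list(cfg.sensitivity_proportions)
    sens = rng.choice(sens_names, size=n_cond,
                      p=[cfg.sensitivity_proportions[s] for s in sens_names])
    classes["sensitivity_class"] = np.where(classes["kinetic_class"] == "none",
                                            "none", sens)

    ci = classes["cell_line"].map(cell_idx).to_numpy()
    rec_level = np.array([expr[cognate[l]][i]
                          for l, i in zip(classes["ligand"], ci)])
    erbb2_level = expr[ERBB2][ci]
    # pERK amplitudes from the receptor model; pAKT linear folds are an
    # independent draw from the same distribution compressed by 1/alpha_true.
    amp = _amplitude(rec_level, erbb2_level, erbb2_center, rng, cfg)
    is_akt = (classes["target"] == "pAKT").to_numpy()
    amp = np.where(is_akt, np.log10(10.0 ** amp / cfg.alpha_true), amp)
    responder = (classes["kinetic_class"] != "none").to_numpy()
    classes["amp_high"] = np.where(responder, amp, 0.0)
    classes["amp_low"] = np.where(
        responder,
        _low_dose_amplitude(classes["amp_high"].to_numpy(),
                            classes["sensitivity_class"].to_numpy(), cfg),
        0.0)

    # measurement cube -------------------------------------------------------
    fold_high = _template(classes["kinetic_class"].to_numpy(), classes["amp_high"].to_numpy())
    fold_low = _template(classes["kinetic_class"].to_numpy(), classes["amp_low"].to_numpy())
    basal_level = np.array([basal_target[t][i] for t, i in zip(classes["target"], ci)])

    blocks = []
    for dose, fold in ((LOW_DOSE, fold_low), (HIGH_DOSE, fold_high)):
        for j, t in enumerate(POST_TIMES):
            for rep in range(1, cfg.n_replicates + 1):
                blocks.append(pd.DataFrame({
                    "cell_line": classes["cell_line"],
                    "ligand": classes["ligand"],
                    "dose": dose,
                    "time": t,
                    "target": classes["target"],
                    "replicate": rep,
                    "value": basal_level + fold[:, j],
                }))
    ctrl_grid = pd.MultiIndex.from_product([cells, TARGETS],
                                           names=["cell_line", "target"]).to_frame(index=False)
    ctrl_basal = np.array([basal_target[t][cell_idx[c]]
                           for c, t in zip(ctrl_grid["cell_line"], ctrl_grid["target"])])
    for rep in range(1, cfg.n_replicates + 1):
        blocks.append(pd.DataFrame({
            "cell_line": ctrl_grid["cell_line"],
            "ligand": CONTROL_LIGAND,
            "dose": np.nan,
            "time": 0,
            "target": ctrl_grid["target"],
            "replicate": rep,
            "value": ctrl_basal,
        }))
    data = pd.concat(blocks, ignore_index=True)
    if cfg.sigma > 0:
        data["value"] = data["value"] + rng.normal(0.0, cfg.sigma, len(data))
    cube = ResponseCube(data)

    truth = GroundTruth(classes=classes, receptor_levels=basal_raw,
                        alpha_true=cfg.alpha_true, sigma=cfg.sigma,
                        seed=seed, config=cfg)
    return PanelBundle(cube=cube, basal=basal, subtypes=subtypes,
                       lrmap=lrmap, truth=truth)
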