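"""Recovery experiments on synthetic panels.

These experiments quantify how well the pipeline recovers the generator's
planted ground truth: class agreement on noiseless and noisy panels, pathway
scale-factor recovery, significance-rule calibration, and correlation-sign
recovery.  They are what the acceptance tests and ``scripts/acceptance.py``
run; each is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .bias import correlate_panel, fit_pathway_scale
from .classify import assign_kinetics, assign_sensitivity
from .constants import HIGH_DOSE, LOG10_1P2
from .metrics import call_significance, compute_fold_changes
from .synthetic import ERBB2, GeneratorConfig, generate_panel, sample_fold_changes


def _run_core(panel, sd_multiplier: float = 2.0, seed: int = 0):
    responses = compute_fold_changes(panel.cube, sd_multiplier=sd_multiplier)
    kinetics, _ = assign_kinetics(responses, seed=seed, sd_multiplier=sd_multiplier)
    sensitivity = assign_sensitivity(responses)
    return responses, kinetics, sensitivity


def zero_noise_recovery(seed: int = 0, n_cell_lines: int = 39,
                        n_ligands: int = 15) -> dict:
    """Agreement (%) between pipeline calls and planted truth on a noiseless panel."""
    panel = generate_panel(n_cell_lines, n_ligands, seed=seed, sigma=0.0)
    responses, kinetics, sensitivity = _run_core(panel, seed=seed)
    expected = panel.truth.expected
    key = ["cell_line", "ligand", "target", "dose"]

    sig = responses.merge(expected, on=key, validate="1:1")
    sig_pct = 100.0 * (sig["significant"] == sig["expected_significant"]).mean()

    kin = kinetics.merge(expected, on=key, validate="1:1")
    kin_pct = 100.0 * (kin["label"] == kin["expected_kinetic"]).mean()

    sens = sensitivity.merge(panel.truth.classes, on=["cell_line", "ligand", "target"],
                             validate="1:1")
    sens_pct = 100.0 * (sens["label"] == sens["sensitivity_class"]).mean()
    return {"significance_agreement_pct": sig_pct,
            "kinetic_agreement_pct": kin_pct,
            "sensitivity_agreement_pct": sens_pct,
            "n_conditions": len(kin)}


def noisy_kinetic_agreement(base_seed: int = 0, n_seeds: int = 10,
                            sigma: float = 0.05, min_amplitude: float = 0.5,
                            n_cell_lines: int = 39, n_ligands: int = 15) -> dict:
    """Kinetic-label agreement on noisy panels.

    Agreement is measured on trajectories that are called significant and
    whose planted template has peak amplitude >= ``min_amplitude`` (the
    regime where the three response shapes are defined), pooled over
    ``n_seeds`` independent panels.
    """
    agree = total = 0
    for s in range(n_seeds):
        seed = base_seed + s
        panel = generate_panel(n_cell_lines, n_ligands, seed=seed, sigma=sigma)
        responses = compute_fold_changes(panel.cube)
        kinetics, _ = assign_kinetics(responses, seed=seed)
        merged = kinetics.merge(panel.truth.expected,
                                on=["cell_line", "ligand", "target", "dose"],
                                validate="1:1")
        mask = (merged["significant"]
                & (merged["expected_amplitude"] >= min_amplitude)
                & (merged["expected_kinetic"] != "none"))
        sub = merged[mask]
        agree += int((sub["label"] == sub["expected_kinetic"]).sum())
        total += len(sub)
    return {"agreement_pct": 100.0 * agree / total, "n_trajectories": total}


def scale_recovery(seed: int = 0, n: int = 500, alpha_true: float = 2.386) -> float:
    """Fit the pathway scale on fold-change samples planted at ``alpha_true``."""
    rng = np.random.default_rng(seed)
    perk = sample_fold_changes(n, rng)
    pakt = perk / alpha_true
    return fit_pathway_scale(pakt, perk)


def min_significant_fold(control_sd: float = LOG10_1P2 / 2,
                         sd_multiplier: float = 2.0, tol: float = 1e-9) -> float:
    """Smallest linear fold-change called significant, found by bisection.

    With the conventional control SD (2·SD = log10 1.2) this calibrates the
    significance rule's fold-change equivalent.
    """
    lo, hi = 1.0, 100.0
    mean = 0.0
    if call_significance(mean + np.log10(lo), mean, control_sd, sd_multiplier):
        return lo
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if call_significance(mean + np.log10(mid), mean, control_sd, sd_multiplier):
            hi = mid
        else:
            lo = mid
    return hi


def correlation_sign_recovery(base_seed: int = 0, n_reps: int = 100,
                              n_cell_lines: int = 39, n_ligands: int = 15) -> dict:
    """Fraction of replicate panels on which the correlation panel recovers
    the planted signs: positive cognate-receptor and negative ErbB2
    correlation of the pERK fold-change, both at p < 0.05."""
    cfg = GeneratorConfig()
    hits = 0
    for r in range(n_reps):
        panel = generate_panel(n_cell_lines, n_ligands, seed=base_seed + r, config=cfg)
        responses = compute_fold_changes(panel.cube)
        ligand = next(iter(panel.lrmap))  # first = most broadly active ligand
        receptor = sorted(panel.lrmap[ligand])[0]
        pan = correlate_panel(
            responses, panel.basal, method="pearson", dose=HIGH_DOSE,
            ligands=[ligand], targets=["pERK"],
            predictors=[(receptor, "expression"), (ERBB2, "expression")])
        pan = pan.set_index("analyte")
        rec = pan.loc[receptor]
        erb = pan.loc[ERBB2]
        if (rec["coefficient"] > 0 and rec["p_value"] < 0.05
                and erb["coefficient"] < 0 and erb["p_value"] < 0.05):
            hits += 1
    return {"recovery_pct": 100.0 * hits / n_reps, "n_reps": n_reps}


def significant_fraction(seed: int = 0, target: str = "pERK",
                         n_cell_lines: int = 39, n_ligands: int = 15) -> dict:
    """Percent of (cell line, ligand) combinations with a significant
    response of ``target`` at either dose on a default synthetic panel."""
    panel = generate_panel(n_cell_lines, n_ligands, seed=seed)
    responses = compute_fold_changes(panel.cube)
    sub = responses[responses["target"] == target]
    per_combo = sub.groupby(["cell_line", "ligand"])["significant"].any()
    return {"pct_significant": 100.0 * per_combo.mean(), "n_combinations": len(per_combo)}
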