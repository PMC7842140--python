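"""End-to-end analysis: train on one strain, transfer to the other.

`run_report` reproduces the full modelling workflow on a cohort table:

1. fit the onset model (OLS of onset week on ln dose) on the training
   strain and validate the fixed parameters on the second strain;
2. globally fit the growth law (free ``a``, ``b``, ``d0``) to the training
   strain's post-onset CE volumes;
3. transfer to the second strain by refitting only the growth exponent
   ``b`` with ``a`` and ``d0`` held at the training estimates;
4. Kaplan-Meier curves per strain/dose group and log-rank comparisons.

The training strain is the first strain in the cohort (first strain spec
of the simulation config for simulated cohorts).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

from .cohort import CohortTable
from .fitting import FitResult, fit_onset_model, fit_volume_model, validate_onset_model
from .survival import km_curve, logrank_test

__all__ = ["analyze_cohort", "run_report", "report_markdown"]

logger = logging.getLogger("braintox")


def analyze_cohort(
    table: CohortTable,
    train_strain: Optional[str] = None,
    transfer_strain: Optional[str] = None,
) -> Dict[str, FitResult]:
    """Run the fit / validate / transfer sequence; returns the four fits."""
    strains = table.strains
    if train_strain is None:
        train_strain = strains[0]
    if transfer_strain is None:
        others = [s for s in strains if s != train_strain]
        transfer_strain = others[0] if others else None

    train = table.for_strain(train_strain)
    onset_fit = fit_onset_model(train.onset_observations(), strain_label=train_strain)
    volume_fit = fit_volume_model(
        train.volume_points(), free={"a", "b", "d0"}, strain_label=train_strain
    )
    results = {"onset_fit": onset_fit, "volume_fit": volume_fit}

    if transfer_strain is not None:
        transfer = table.for_strain(transfer_strain)
        results["onset_validation"] = validate_onset_model(
            onset_fit.params, transfer.onset_observations()
        )
        results["transfer_fit"] = fit_volume_model(
            transfer.volume_points(),
            free={"b"},
            fixed={"a": volume_fit.params.a, "d0": volume_fit.params.d0},
            strain_label=transfer_strain,
        )
    return results


def _survival_summary(table: CohortTable) -> dict:
    records = table.survival_records()
    groups: Dict[str, list] = {}
    for r in records:
        groups.setdefault(r.group_label, []).append(r)

    summary = {"groups": {}, "curves": {}, "logrank": []}
    for label in sorted(groups):
        recs = groups[label]
        summary["groups"][label] = {
            "n": len(recs),
            "events": sum(r.event for r in recs),
            "last_weeks": sorted(r.time for r in recs),
        }
        summary["curves"][label] = km_curve(recs)

    # Pairwise log-rank: highest vs lowest irradiated dose within each
    # strain, and highest-dose group across strains (when both exist).
    by_strain: Dict[str, List[str]] = {}
    for label in groups:
        strain, dose = label.rsplit(":", 1)
        if float(dose) > 0:
            by_strain.setdefault(strain, []).append(label)
    def _dose(label: str) -> float:
        return float(label.rsplit(":", 1)[1])

    tops = []
    for strain in sorted(by_strain):
        labels = sorted(by_strain[strain], key=_dose)
        tops.append(labels[-1])
        if len(labels) >= 2:
            _append_logrank(summary, groups, labels[-1], labels[0])
    if len(tops) == 2:
        _append_logrank(summary, groups, tops[0], tops[1])
    return summary


def _append_logrank(summary: dict, groups: dict, label_a: str, label_b: str) -> None:
    try:
        stat, p = logrank_test(groups[label_a], groups[label_b])
    except ValueError as exc:  # e.g. no events in either group
        summary["logrank"].append(
            {"group_a": label_a, "group_b": label_b, "error": str(exc)}
        )
        return
    summary["logrank"].append(
        {"group_a": label_a, "group_b": label_b, "chi_square": stat, "p_value": p}
    )


def run_report(
    table: CohortTable,
    train_strain: Optional[str] = None,
    transfer_strain: Optional[str] = None,
) -> dict:
    """Full pipeline summary as a JSON-serialisable dictionary."""
    fits = analyze_cohort(table, train_strain, transfer_strain)
    report = {
        "n_mice": len(table),
        "strains": table.strains,
        "fits": {name: fr.to_dict() for name, fr in fits.items()},
        "survival": _survival_summary(table),
    }
    logger.info(
        "report: trained on %s (volume R²=%.3f, %d points)",
        fits["volume_fit"].params.strain_label,
        fits["volume_fit"].r_squared,
        fits["volume_fit"].n_points,
    )
    return report


def report_markdown(report: dict) -> str:
    """Render the report dictionary as a short markdown summary."""
    lines = ["# Dose-volume response report", ""]
    lines.append(f"Cohort: {report['n_mice']} mice, strains {', '.join(report['strains'])}.")
    lines.append("")
    lines.append("## Model fits")
    lines.append("")
    lines.append("| step | strain | a [1/Gy] | b | D0 [Gy] | t1 [wk] | t2 [wk] | R² | n |")
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for name, fit in report["fits"].items():
        p = fit["params"]

        def fmt(x, nd=4):
            return "-" if x is None else f"{x:.{nd}g}"

        lines.append(
            f"| {name} | {fit['strain']} | {fmt(p['a'])} | {fmt(p['b'], 3)} "
            f"| {fmt(p['d0'], 3)} | {fmt(p['t1'], 4)} | {fmt(p['t2'], 4)} "
            f"| {fit['r_squared']:.3f} | {fit['n_points']} |"
        )
    lines.append("")
    lines.append("## Survival")
    lines.append("")
    lines.append("| group | n | events | last weeks |")
    lines.append("|---|---|---|---|")
    for label, g in report["survival"]["groups"].items():
        weeks = ", ".join(f"{w:g}" for w in g["last_weeks"])
        lines.append(f"| {label} | {g['n']} | {g['events']} | {weeks} |")
    lines.append("")
    for lr in report["survival"]["logrank"]:
        if "error" in lr:
            lines.append(f"- log-rank {lr['group_a']} vs {lr['group_b']}: {lr['error']}")
        else:
            lines.append(
                f"- log-rank {lr['group_a']} vs {lr['group_b']}: "
                f"chi² = {lr['chi_square']:.3f}, p = {lr['p_value']:.4f}"
            )
    lines.append("")
    return "\n".join(lines)
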