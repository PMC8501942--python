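"""End-to-end analysis report: equilibria -> stability -> critical step ->
normal form -> control table, with per-stage failure capture.

Every number in the bundle is the direct output of a module operation;
the presentation layer never recomputes anything.  The bundle is a plain
JSON-serialisable dict, deterministic for identical inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import equilibria, hybrid_control, linear_stability, ns_normal_form
from .model_core import ModelParams, validate

__all__ = ["run_report", "write_report"]

log = logging.getLogger("planktonmap")

_DEFAULT_H_LIST = (0.488895690, 0.588895690, 0.688895690,
                   0.788895690, 0.888895690, 0.988895690)


def _state(s) -> list[float] | None:
    return None if s is None else [float(s.p), float(s.z)]


def run_report(params: ModelParams,
               control_h_list=_DEFAULT_H_LIST) -> dict:
    """Run the full analysis pipeline on one parameter set.

    A failing stage records its error under ``stages`` and downstream
    stages that depend on it are skipped with a reason.
    """
    bundle: dict = {"params": params.as_dict(), "stages": {}}
    stages = bundle["stages"]

    rep = validate(params)
    bundle["validation"] = {"hard_errors": list(rep.hard_errors),
                            "warnings": list(rep.warnings)}
    if not rep.ok:
        stages["validation"] = "failed"
        return bundle
    stages["validation"] = "ok"

    log.info("equilibria: scanning F on (0, k]")
    try:
        box = equilibria.bounding_box(params)
        eqs = equilibria.equilibrium_set(params)
        thm = equilibria.existence_report(params)
        bundle["equilibria"] = {
            "box": {"p_max": box.p_max, "z_max": box.z_max},
            "trivial": _state(eqs.trivial),
            "axial": {"point": _state(eqs.axial), "exists": eqs.axial_exists},
            "interior": {
                "point": _state(eqs.interior),
                "exists": eqs.interior_exists,
                "residuals": (None if eqs.interior_residuals is None
                              else list(eqs.interior_residuals)),
                "unique": eqs.unique,
            },
            "existence": {
                "r_gt_q1E": thm.r_gt_q1E,
                "F0_sign": thm.F0_sign,
                "Fk_sign": thm.Fk_sign,
                "margin_at_0": thm.margin_at_0,
                "margin_at_k": thm.margin_at_k,
                "verdict": thm.verdict,
            },
        }
        stages["equilibria"] = "ok"
    except Exception as exc:  # pragma: no cover - defensive
        stages["equilibria"] = f"failed: {exc}"
        return bundle

    log.info("stability: Jury classification of each fixed point")
    stability: dict = {}
    for which in ("trivial", "axial", "interior"):
        try:
            cls, diag = linear_stability.classify_equilibrium(params, which)
            stability[which] = {"verdict": cls.verdict,
                                "lemma_case": cls.lemma_case,
                                "diagnostics": diag}
        except ValueError as exc:
            stability[which] = {"verdict": "absent", "reason": str(exc)}
    bundle["stability"] = stability
    stages["stability"] = "ok"

    log.info("critical step: locating the Dt(h) = 1 crossing")
    try:
        cs = linear_stability.critical_step(params)
        bundle["critical_step"] = {
            "h_star": cs.h_star,
            "residual": cs.residual,
            "transversality": cs.transversality,
            "non_resonant": cs.non_resonant,
            "trace": cs.trace_at_star,
        }
        stages["critical_step"] = "ok"
    except linear_stability.NoCrossingError as exc:
        stages["critical_step"] = f"no crossing: {exc}"
        stages["normal_form"] = "skipped (no critical step)"
        stages["control_table"] = "skipped (no critical step)"
        return bundle

    log.info("normal form: theta coefficients and first Lyapunov quantity")
    try:
        nf = ns_normal_form.lyapunov_coefficient(params, cs.h_star)
        bundle["normal_form"] = {
            "h_star": nf.h_star,
            "ell": nf.ell,
            "wp": nf.wp,
            "theta20": [nf.theta20.real, nf.theta20.imag],
            "theta11": [nf.theta11.real, nf.theta11.imag],
            "theta02": [nf.theta02.real, nf.theta02.imag],
            "theta21": [nf.theta21.real, nf.theta21.imag],
            "omega": nf.omega,
            "omega_uncertainty": nf.omega_uncertainty,
            "verdict": nf.verdict,
        }
        stages["normal_form"] = "ok"
    except ns_normal_form.ResonanceError as exc:
        stages["normal_form"] = f"degenerate: {exc}"

    log.info("control table: gain intervals for both methods")
    try:
        bundle["control_table"] = hybrid_control.comparison_table(
            params, control_h_list)
        stages["control_table"] = "ok"
    except Exception as exc:
        stages["control_table"] = f"failed: {exc}"
    return bundle


def write_report(bundle: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_plain(bundle), indent=2, sort_keys=True) + "\n")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
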