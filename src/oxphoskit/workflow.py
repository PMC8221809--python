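"""End-to-end convenience: traces -> steady states -> OXPHOS summary."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import oxphos, respirometry as resp

__all__ = ["ck_assay_summary"]


def ck_assay_summary(
    ck_trace: resp.OxygenTrace,
    ck_events: Sequence[resp.EventMark],
    ets_trace: resp.OxygenTrace,
    ets_events: Sequence[resp.EventMark],
    label_forces: Mapping[str, float],
    fccp_label: str = "FC",
    residual_label: str = "Ant",
    ets_fccp_labels: Sequence[str] | None = None,
    policy: resp.WindowPolicy = resp.WindowPolicy(),
    smoothing_halfwidth: float = 20.0,
    jh_oxphos_force: float = oxphos.JH_OXPHOS_FORCE,
) -> oxphos.OxphosSummary:
    """Run both protocols through flux, plateau extraction and the metrics.

    ``label_forces`` maps CK-protocol segment labels (PCr steps) to their
    clamp forces in kJ/mol; the non-mito residual is subtracted from both
    protocols before any ratio is formed.
    """
    if policy.guard_s < smoothing_halfwidth:
        from dataclasses import replace

        policy = replace(policy, guard_s=smoothing_halfwidth)
    ck_flux = resp.compute_flux(ck_trace, smoothing_halfwidth)
    ck_states = resp.extract_steady_states(ck_trace, ck_flux, ck_events, policy)
    ck_states = resp.correct_nonmito(ck_states, residual_label)
    by_label = {s.label: s for s in ck_states}

    points = sorted(
        ((label_forces[lbl], by_label[lbl].jo2) for lbl in label_forces),
        key=lambda p: -p[0],
    )
    fccp_rates = [s.jo2 for s in ck_states if s.label.startswith(fccp_label)]
    if not fccp_rates:
        raise oxphos.MetricsError(f"no {fccp_label!r} state in the CK protocol")
    kin = oxphos.OxphosKinetics(points=points, fccp_dgatp=max(fccp_rates))

    ets_flux = resp.compute_flux(ets_trace, smoothing_halfwidth)
    ets_states = resp.extract_steady_states(ets_trace, ets_flux, ets_events, policy)
    ets_states = resp.correct_nonmito(ets_states, residual_label)
    if ets_fccp_labels is None:
        ets_rates = [
            s.jo2 for s in ets_states if s.label.startswith("FC")
        ]
    else:
        wanted = set(ets_fccp_labels)
        ets_rates = [s.jo2 for s in ets_states if s.label in wanted]

    return oxphos.summarize(kin, ets_rates, force=jh_oxphos_force)
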