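"""Mutation timing (ATMA), trajectory prediction and clone-size metrics.

Given the selected clonal structure and each clone's MAP fitness, the
acquisition age of each variant (ATMA) is the age at which the clone was
a single cell, found by maximizing the binomial likelihood of the
trajectory under the isolated deterministic growth model with a fixed
wild-type pool of N stem cells.  Fitness and timing combine into
MACS120 = exp(s * (120 - ATMA)), the predicted clone size at age 120,
and into isolated vs context-aware VAF forecasts whose difference
quantifies clonal competition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import growth
from .errors import ParameterError
from .growth import GrowthModelParams, clone_size, isolated_vaf, macs120
from .inference import CloneEstimate, binom_logpmf
from .io import ParticipantData, Trajectory

__all__ = [
    "Prediction",
    "ParticipantMetrics",
    "estimate_atma",
    "predict_isolated",
    "predict_context",
    "compare_isolated_vs_context",
    "participant_metrics",
    "zscore_metrics",
]


@dataclass
class Prediction:
    """Per-variant forecast at a query age under both growth models."""

    label: str
    participant_id: str
    s: float
    atma: float
    isolated_vaf: float
    context_vaf: float
    macs: float
    log_macs: float

    @property
    def delta_vaf(self) -> float:
        return self.isolated_vaf - self.context_vaf


@dataclass
class ParticipantMetrics:
    """Participant-level summary metrics used by the association stages."""

    participant_id: str
    max_vaf: float
    max_fitness: float
    macs120: float
    log_macs120: float
    flags: list = field(default_factory=list)


def estimate_atma(
    trajectory: Trajectory,
    s: float,
    params: GrowthModelParams | None = None,
    s_min_identifiable: float = 0.0,
    tol: float = 1e-6,
):
    """Continuous maximum-likelihood acquisition age of one variant.

    Maximizes the binomial log-likelihood of the observed read counts
    under the isolated deterministic VAF model, searching ATMA in
    ``[0, age of first observation]`` to ``tol`` years.  Returns
    ``(atma, flags)``; ``atma`` is ``None`` when unidentifiable
    (fitness at or below the grid minimum, or no alt reads at all).
    """
    params = params or GrowthModelParams()
    flags: list[str] = []
    if s <= s_min_identifiable:
        return None, ["fitness-at-grid-minimum"]
    if float(np.sum(trajectory.alt_reads)) == 0.0:
        return None, ["all-zero-alt-reads"]

    ages, ao, d = trajectory.ages, trajectory.alt_reads, trajectory.depths
    hi = float(ages[0])

    def nll(a):
        x = np.where(ages >= a, np.exp(s * (ages - a)), 0.0)
        p = np.where(
            x > 0,
            x / (params.diploid_factor * (params.n_wildtype + x)),
            params.error_floor,
        )
        return -float(binom_logpmf(ao, d, p).sum())

    if hi <= 0:
        return 0.0, ["boundary"]
    res = minimize_scalar(nll, bounds=(0.0, hi), method="bounded", options={"xatol": tol})
    atma = float(min(max(res.x, 0.0), hi))
    # bounded Brent can stall a little inside the bracket even when the
    # optimum sits on the boundary; accept a boundary only if strictly better
    for edge in (0.0, hi):
        if nll(edge) < nll(atma):
            atma = edge
    if atma <= tol or atma >= hi - tol:
        atma = 0.0 if atma <= tol else hi
        flags.append("boundary")
    return atma, flags


def predict_isolated(s: float, atma: float, t: float, params: GrowthModelParams | None = None):
    """Isolated-growth VAF forecast x/(2(N+x)) at age ``t``."""
    return isolated_vaf(s, atma, t, params)


def predict_context(
    estimate: CloneEstimate,
    t: float,
    params: GrowthModelParams | None = None,
):
    """Context-aware VAF forecast for every variant of a participant.

    The denominator contains N plus the summed sizes of every clone's
    lead variant.  Variants without an acquisition-age estimate are
    excluded (returned in the second element).
    """
    params = params or GrowthModelParams()
    excluded = []
    leads = []
    for clone in estimate.clones:
        a = clone.atma.get(clone.lead)
        if a is None:
            excluded.extend(clone.variants)
            continue
        leads.append((clone.map_s, a))
    total_lead = sum(clone_size(s, a, t) for s, a in leads)

    vafs: dict[str, float] = {}
    for clone in estimate.clones:
        for lab in clone.variants:
            if lab in excluded:
                continue
            a = clone.atma.get(lab)
            if a is None:
                excluded.append(lab)
                continue
            x = clone_size(clone.map_s, a, t)
            vafs[lab] = growth.context_vaf(x, total_lead, params)
    return vafs, excluded


def compare_isolated_vs_context(
    estimates,
    t: float | None = None,
    params: GrowthModelParams | None = None,
):
    """Cohort-wide isolated vs context-aware forecast comparison.

    Returns ``(per_variant_table, summary)``; the summary reports the
    mean absolute VAF difference at the horizon age and the fraction of
    participants whose largest difference exceeds 0.20.
    """
    params = params or GrowthModelParams()
    t = params.max_age if t is None else t
    rows = []
    per_participant_max: dict[str, float] = {}
    for est in estimates:
        ctx, _excluded = predict_context(est, t, params)
        for clone in est.clones:
            for lab in clone.variants:
                if lab not in ctx:
                    continue
                a = clone.atma[lab]
                iso = predict_isolated(clone.map_s, a, t, params)
                delta = iso - ctx[lab]
                m, logm = macs120(clone.map_s, a, params)
                rows.append(
                    Prediction(
                        label=lab,
                        participant_id=est.participant_id,
                        s=clone.map_s,
                        atma=a,
                        isolated_vaf=iso,
                        context_vaf=ctx[lab],
                        macs=m,
                        log_macs=logm,
                    )
                )
                pid = est.participant_id
                per_participant_max[pid] = max(per_participant_max.get(pid, 0.0), abs(delta))
    table = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "variant": [r.label for r in rows],
            "s": [r.s for r in rows],
            "atma": [r.atma for r in rows],
            "isolated_vaf": [r.isolated_vaf for r in rows],
            "context_vaf": [r.context_vaf for r in rows],
            "delta_vaf": [r.delta_vaf for r in rows],
            "macs120": [r.macs for r in rows],
            "log_macs120": [r.log_macs for r in rows],
        }
    )
    n_part = len(per_participant_max)
    summary = {
        "mean_abs_delta": float(np.mean(np.abs(table["delta_vaf"]))) if len(table) else 0.0,
        "frac_participants_delta_gt_020": (
            float(np.mean([v > 0.20 for v in per_participant_max.values()])) if n_part else 0.0
        ),
        "n_variants": len(table),
        "n_participants": n_part,
    }
    return table, summary


def participant_metrics(
    participant: ParticipantData,
    estimate: CloneEstimate | None,
    params: GrowthModelParams | None = None,
) -> ParticipantMetrics:
    """Max observed VAF, max MAP fitness and max MACS120 of a participant.

    Z-scoring happens cohort-wide at the analysis stage
    (:func:`zscore_metrics`).  Participants without variants get zeros
    and a flag.
    """
    params = params or GrowthModelParams()
    if estimate is None or not participant.trajectories:
        return ParticipantMetrics(participant.participant_id, 0.0, 0.0, 0.0, 0.0, ["no-variants"])
    max_vaf = max(float(np.max(t.vafs)) for t in participant.trajectories)
    max_s = estimate.max_map_s
    # a clone with fitness at the grid minimum has no ATMA, but its MACS120
    # is exp(0 * ...) = 1 regardless of timing, so 1 is the defined floor
    best = (0.0, 1.0)  # (log_macs, macs)
    flags = []
    for clone in estimate.clones:
        a = clone.atma.get(clone.lead)
        if a is None:
            flags.append(f"clone {clone.variants}: no ATMA, MACS floored at 1")
            continue
        m, logm = macs120(clone.map_s, a, params)
        if logm > best[0]:
            best = (logm, m)
    return ParticipantMetrics(
        participant_id=participant.participant_id,
        max_vaf=max_vaf,
        max_fitness=max_s,
        macs120=best[1],
        log_macs120=best[0],
        flags=flags,
    )


def zscore_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Z-score max_vaf, max_fitness and log-scale MACS120 over a cohort.

    MACS120 spans many orders of magnitude, so its z-score is computed on
    the log scale (the raw value is retained).
    """
    out = metrics.copy()
    for col, zcol in [
        ("max_vaf", "max_vaf_z"),
        ("max_fitness", "max_fitness_z"),
        ("log_macs120", "macs120_z"),
    ]:
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[zcol] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out
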