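"""Phase-aware, growth-state-stratified drug-survival analysis.

An experiment with a drug phase is split at the exposure onset: the
pre-exposure phase characterises each lineage's growth state (division
count over the drug-free window), and the post-exposure phase yields
survival curves stratified by that state.  Lineages already dead (or out of
observation) at the onset are excluded from the post phase.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np

from mmlineage.io import DEATH, EventRecord, validate_events
from mmlineage.stats import SurvivalCurve

__all__ = ["split_phases", "stratified_survival", "pooled_survival"]


def split_phases(
    events: Iterable[EventRecord], exposure_start_h: float
) -> tuple[list[EventRecord], list[EventRecord]]:
    """Split an event table at drug-exposure onset.

    The pre phase holds events in the half-open window [0, exposure_start_h)
    for every channel; the post phase holds events at or after the onset
    (an event at exactly the onset belongs to the post phase), restricted to
    channels still alive and under observation at the onset.

    Returns (pre_events, post_events).
    """
    by_channel = validate_events(events)
    t_end = max(recs[-1].time_h for recs in by_channel.values())
    if not (0 < exposure_start_h < t_end):
        raise ValueError(
            f"exposure_start_h = {exposure_start_h} must lie inside the "
            f"observation span (0, {t_end})"
        )
    pre: list[EventRecord] = []
    post: list[EventRecord] = []
    for recs in by_channel.values():
        last = recs[-1]
        alive_at_onset = last.time_h >= exposure_start_h
        for r in recs:
            if r.time_h < exposure_start_h:
                pre.append(r)
            elif alive_at_onset:
                post.append(r)
    return pre, post


def stratified_survival(
    post_events: Iterable[EventRecord],
    labels: Mapping[str, str],
    exposure_start_h: float = 0.0,
    dt_h: float = 1.0 / 6.0,
) -> dict[str, SurvivalCurve]:
    """Survival curves per growth-state stratum after drug exposure.

    Each stratum's surviving fraction is normalised to the stratum's lineage
    count at exposure onset, on a frame grid measured from the onset, with
    binomial standard errors sqrt(S (1-S) / n0).  ``labels`` maps channel_id
    to its stratum (e.g. the fast/slow classification from pre-exposure
    division counts); channels missing from ``labels`` raise.
    """
    by_channel = validate_events(post_events)
    strata: dict[str, list[float]] = {}
    horizon = 0.0
    for cid, recs in by_channel.items():
        if cid not in labels:
            raise KeyError(f"channel {cid!r} has no stratum label")
        last = recs[-1]
        death = last.time_h if last.event == DEATH else np.inf
        strata.setdefault(labels[cid], []).append(death - exposure_start_h)
        horizon = max(horizon, last.time_h - exposure_start_h)
    if len(strata) < 2:
        warnings.warn(
            f"only one stratum present ({list(strata)}); single-stratum output"
        )
    n_bins = int(np.ceil(horizon / dt_h - 1e-9))
    times = np.arange(n_bins + 1) * dt_h
    out: dict[str, SurvivalCurve] = {}
    for label, deaths in strata.items():
        d = np.asarray(deaths)
        n0 = d.size
        frac = (d[None, :] > times[:, None] + 1e-12).sum(axis=1) / n0
        # a death exactly at the onset still counts the lineage at onset
        frac[0] = 1.0 if n0 else 0.0
        frac = np.minimum.accumulate(frac)
        se = np.sqrt(frac * (1 - frac) / n0)
        out[label] = SurvivalCurve(
            times=times, surviving_fraction=frac, se=se, n0=n0
        )
    return out


def pooled_survival(curves: Mapping[str, SurvivalCurve]) -> SurvivalCurve:
    """Size-weighted average of stratum curves: the pooled survival curve.

    The strata partition the lineages alive at onset, so the weighted
    average of their surviving fractions reproduces the unstratified curve
    exactly.
    """
    labels = list(curves)
    times = curves[labels[0]].times
    n_total = sum(curves[k].n0 for k in labels)
    frac = sum(curves[k].surviving_fraction * curves[k].n0 for k in labels) / n_total
    se = np.sqrt(frac * (1 - frac) / n_total)
    return SurvivalCurve(
        times=times, surviving_fraction=frac, se=se, n0=n_total
    )
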