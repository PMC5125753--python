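"""Per-track summaries and population statistics of fast particle movement.

A track's speed is the mean of its frame-to-frame velocities, its
direction is the vector from the initial to the final position, and its
distance from the anterior is measured at its initial position.  The
population-level questions — is there an excess of anterior-directed
movements, is the net anterior displacement nonzero, do genotypes differ
in speed — are answered with an exact one-tailed binomial test, Wilcoxon
tests and a mixed-effects model with oocyte/movie random intercepts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (AnteriorAxis, DirectionalityResult, MobileFractionResult,
                        ParameterError, Track, TrackSummary)
from . import stats as _stats

__all__ = [
    "summarize_track",
    "summarize_tracks",
    "classify_direction3",
    "directional_bias",
    "mobile_fraction",
    "reversal_fraction",
    "count_reversals",
    "compare_speed_distributions",
]


def classify_direction3(angle: float, axis: AnteriorAxis,
                        sector_half_angle: float = 45.0) -> str:
    """Classify a movement angle (degrees, vs +x) as anterior/posterior/lateral.

    Anterior means within ``sector_half_angle`` degrees of the anterior
    direction; posterior is the symmetric sector about the posterior
    direction; everything else is lateral.
    """
    if not (0.0 < sector_half_angle < 90.0):
        raise ParameterError("sector_half_angle must be in (0, 90)")
    ant = axis.anterior_unit
    ant_angle = np.degrees(np.arctan2(ant[1], ant[0]))
    diff = abs((angle - ant_angle + 180.0) % 360.0 - 180.0)
    if diff <= sector_half_angle:
        return "anterior"
    if diff >= 180.0 - sector_half_angle:
        return "posterior"
    return "lateral"


def count_reversals(track: Track, axis: AnteriorAxis,
                    min_sustained: int = 2, min_step_um: float = 0.0) -> int:
    """Count sustained sign changes of the along-axis step component.

    A reversal is counted when the sign of the step projection on the
    axis changes and the new sign persists for at least ``min_sustained``
    consecutive frames, which suppresses single-frame flips caused by
    localisation noise.  Steps shorter than ``min_step_um`` along the
    axis are ignored as stationary.
    """
    steps = np.diff(track.positions, axis=0)
    proj = steps @ np.asarray(axis.posterior_unit, dtype=float)
    signs = np.sign(proj)
    signs[np.abs(proj) <= min_step_um] = 0.0
    signs = signs[signs != 0.0]
    if signs.size < 2:
        return 0
    n_rev = 0
    cur = signs[0]
    i = 1
    while i < len(signs):
        if signs[i] == cur:
            i += 1
            continue
        run = 1
        while i + run < len(signs) and signs[i + run] == signs[i]:
            run += 1
        if run >= min_sustained:
            n_rev += 1
            cur = signs[i]
        i += run
    return n_rev


def summarize_track(track: Track, axis: AnteriorAxis,
                    sector_half_angle: float = 45.0) -> TrackSummary:
    """Compute the per-track summary statistics.

    ``mean_speed`` is the mean over consecutive frame pairs of step
    length / Δt; ``anterior_displacement_rate`` is the anterior component
    of the net (initial→final) displacement divided by the track
    duration, so its sign defines the binary direction class.
    """
    pos = track.positions
    steps = np.diff(pos, axis=0)
    dts = np.diff(track.t)
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    mean_speed = float(np.mean(step_len / dts))
    track_distance = float(np.sum(step_len))
    net = pos[-1] - pos[0]
    duration = float(track.t[-1] - track.t[0])
    ant_net = axis.anterior_component(net)
    angle = float(np.degrees(np.arctan2(net[1], net[0])))
    direction2 = "anterior" if ant_net > 0 else "posterior"
    return TrackSummary(
        track_id=track.track_id,
        mean_speed=mean_speed,
        track_distance=track_distance,
        direction_angle=angle,
        direction2=direction2,
        direction3=classify_direction3(angle, axis, sector_half_angle),
        initial_distance_from_anterior=axis.distance_from_anterior(pos[0]),
        anterior_displacement_rate=ant_net / duration,
        n_reversals=count_reversals(track, axis),
        oocyte_id=track.oocyte_id,
        movie_id=track.movie_id,
        genotype=track.genotype,
    )


def summarize_tracks(tracks: Sequence[Track], axis: AnteriorAxis,
                     **kwargs) -> list[TrackSummary]:
    return [summarize_track(tr, axis, **kwargs) for tr in tracks]


def directional_bias(summaries: Sequence[TrackSummary],
                     bins_um: Sequence[float] = (5.0, 10.0, 40.0),
                     windchart_bin_deg: float = 30.0,
                     axis: AnteriorAxis = AnteriorAxis()) -> DirectionalityResult:
    """Population directionality: counts, binomial test and windchart.

    The binary anterior/posterior split follows the sign of the net
    anterior displacement component.  The one-tailed binomial test asks
    whether the anterior fraction exceeds 50%; the one-sample Wilcoxon
    asks whether the anterior displacement rate differs from zero
    (two-sided).  Distance bins use the track's initial distance from
    the anterior, with the last bin edge as an outer cutoff.
    """
    if len(summaries) == 0:
        raise ParameterError("directional_bias needs >= 1 track summary")
    if 360.0 % windchart_bin_deg != 0:
        raise ParameterError("windchart_bin_deg must divide 360")
    rates = np.array([s.anterior_displacement_rate for s in summaries])
    n_ant = int(np.sum(rates > 0))
    n_post = len(summaries) - n_ant
    counts3: dict[str, int] = {"anterior": 0, "posterior": 0, "lateral": 0}
    for s in summaries:
        counts3[s.direction3] += 1

    edges = [0.0, *bins_um]
    dist = np.array([s.initial_distance_from_anterior for s in summaries])
    per_bin = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (dist >= lo) & (dist < hi)
        per_bin.append((int(np.sum(in_bin & (rates > 0))),
                        int(np.sum(in_bin & (rates <= 0)))))

    # windchart of direction angles measured from the anterior direction
    ant = axis.anterior_unit
    ant_angle = np.degrees(np.arctan2(ant[1], ant[0]))
    rel = np.array([(s.direction_angle - ant_angle) % 360.0 for s in summaries])
    wedges = np.arange(0.0, 360.0 + windchart_bin_deg, windchart_bin_deg)
    hist, _ = np.histogram(rel, bins=wedges)
    freq = hist / hist.sum()

    return DirectionalityResult(
        n_tracks=len(summaries), n_anterior=n_ant, n_posterior=n_post,
        counts3=counts3, bin_edges_um=list(edges), counts_per_bin=per_bin,
        windchart_bin_deg=windchart_bin_deg, windchart_edges=wedges,
        windchart_freq=freq,
        binomial_p=_stats.binomial_one_tailed(n_ant, len(summaries)),
        wilcoxon_net_p=_stats.wilcoxon_one_sample(rates, mu=0.0),
    )


def mobile_fraction(detections: pd.DataFrame, move_threshold_um: float = 0.5,
                    window_s: float = 5.0,
                    axis: Optional[AnteriorAxis] = None,
                    anterior_exclusion_um: float = 0.0) -> MobileFractionResult:
    """Fraction of particles that move actively within a time window.

    ``detections`` must have columns ``particle_id, t_s, x_um, y_um``.
    A particle counts as mobile iff its maximum displacement from its
    first observed position within the window exceeds
    ``move_threshold_um``.  Particles whose first position lies within
    ``anterior_exclusion_um`` of the anterior are excluded (the very
    anterior is too dense for single-particle discrimination).
    """
    required = {"particle_id", "t_s", "x_um", "y_um"}
    missing = required - set(detections.columns)
    if missing:
        raise ParameterError(f"detections missing columns: {sorted(missing)}")
    if detections.empty:
        raise ParameterError("no particle detections provided")
    n_mobile = 0
    n_total = 0
    for _, grp in detections.groupby("particle_id"):
        grp = grp.sort_values("t_s")
        t0 = grp["t_s"].iloc[0]
        grp = grp[grp["t_s"] <= t0 + window_s]
        if len(grp) < 2:
            continue
        p0 = grp[["x_um", "y_um"]].iloc[0].to_numpy()
        if axis is not None and anterior_exclusion_um > 0:
            if axis.distance_from_anterior(p0) < anterior_exclusion_um:
                continue
        disp = np.hypot(grp["x_um"].to_numpy() - p0[0], grp["y_um"].to_numpy() - p0[1])
        n_total += 1
        if np.max(disp) > move_threshold_um:
            n_mobile += 1
    if n_total == 0:
        raise ParameterError("no particles with >= 2 observations in the window")
    return MobileFractionResult(mobile_fraction=n_mobile / n_total,
                                n_particles=n_total, n_mobile=n_mobile,
                                window_s=window_s, move_threshold_um=move_threshold_um)


def reversal_fraction(tracks: Sequence[Track], axis: AnteriorAxis,
                      min_sustained: int = 2) -> float:
    """Fraction of tracks with at least one sustained direction reversal."""
    if len(tracks) == 0:
        return 0.0
    n_rev = sum(count_reversals(tr, axis, min_sustained=min_sustained) > 0
                for tr in tracks)
    return n_rev / len(tracks)


def compare_speed_distributions(groupA: Sequence[TrackSummary],
                                groupB: Sequence[TrackSummary]) -> tuple[float, float]:
    """Compare per-track mean speeds between two genotypes.

    Returns ``(wilcoxon_p, lmm_p)``: the two-sided rank-sum p-value and
    the p-value of the genotype fixed effect in a mixed model with
    random intercepts for oocyte and for movie within oocyte
    (likelihood-ratio test).
    """
    if len(groupA) == 0 or len(groupB) == 0:
        raise ParameterError("both groups must be non-empty")
    a = np.array([s.mean_speed for s in groupA])
    b = np.array([s.mean_speed for s in groupB])
    wilcoxon_p = _stats.wilcoxon_rank_sum(a, b)
    response = np.concatenate([a, b])
    group = np.array(["A"] * len(a) + ["B"] * len(b))
    oocyte = np.array([s.oocyte_id for s in groupA] + [s.oocyte_id for s in groupB])
    movie = np.array([s.movie_id for s in groupA] + [s.movie_id for s in groupB])
    lmm_p = _stats.lmm_fixed_effect_p(response, group, oocyte, movie)
    return wilcoxon_p, lmm_p
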