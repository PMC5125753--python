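"""Seeded generators for synthetic tracks, recovery curves and spot images.

Each generator consumes a parameter dataclass plus a single integer seed
and returns both the synthetic observations and a ground-truth table, so
that every downstream estimator can be exercised against known truth.

The generators encode the statistical structure the analyses assume:

* tracks are near-unidirectional runs whose direction is drawn once per
  track (anterior or posterior hemicircle by a Bernoulli draw, jittered
  laterally), with rare sustained reversals;
* recovery/decay time courses are the sum of a fast nonspecific and a
  slow RNA-specific exponential, optionally degraded by acquisition
  photobleaching and slow MCP dissociation from the MS2 stem-loops;
* images are fields of separable 2-D Lorentzian spots (the effective
  STED point-spread profile) on a noisy, optionally tilted background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datatypes import AnteriorAxis, IntensitySeries, ParameterError, StedImage, Track

__all__ = [
    "TrackSimParams",
    "RecoverySimParams",
    "ImageSimParams",
    "simulate_tracks",
    "simulate_recovery",
    "simulate_sted_image",
    "simulate_two_channel",
]

_LN2 = np.log(2.0)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


@dataclass
class TrackSimParams:
    """Parameters of the fast-particle track generator.

    Defaults emulate wild-type fast particles: mean run speed 0.78 μm/s,
    a slight anterior bias of 52.6% and ~2% of tracks reversing, with
    short runs of a few frames at 0.5 s intervals.
    """

    n_tracks: int = 400
    frame_interval: float = 0.5  # s
    n_frames_range: tuple[int, int] = (4, 8)
    speed_mean: float = 0.78  # μm/s
    speed_sd: float = 0.2  # μm/s
    anterior_bias: float = 0.526
    lateral_spread: float = 30.0  # degrees s.d. about the chosen axis
    mobile_prob: float = 1.0
    reversal_prob: float = 0.02  # per-frame
    position_noise_sd: float = 0.02  # μm
    start_depth_um: float = 40.0  # starts uniform within this distance of the anterior
    seed: int = 0

    def validate(self) -> None:
        for name in ("anterior_bias", "mobile_prob", "reversal_prob"):
            _check_prob(name, getattr(self, name))
        if self.speed_mean <= 0:
            raise ParameterError("speed_mean must be > 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.n_tracks < 1:
            raise ParameterError("n_tracks must be >= 1")
        lo, hi = self.n_frames_range
        if lo < 2 or hi < lo:
            raise ParameterError("n_frames_range must satisfy 2 <= min <= max")
        if self.speed_sd < 0 or self.position_noise_sd < 0 or self.lateral_spread < 0:
            raise ParameterError("scales must be >= 0")


@dataclass
class RecoverySimParams:
    """Forward model of a FRAP recovery or photo-conversion decay.

    The noiseless photo-conversion curve is
    ``F_IM + C_NS exp(-ln2 t/tau_NS) + C_RNA exp(-ln2 t/tau_RNA)`` and
    the FRAP curve is its ``1 - F_IM - ... `` counterpart.  Acquisition
    photobleaching multiplies the whole signal by ``exp(-p t)``; MCP
    dissociation (photo-conversion only) multiplies the RNA-specific
    part by ``exp(-koff t)``.
    """

    mode: Literal["frap", "photoconversion"] = "photoconversion"
    F_IM: float = 0.63
    C_NS: float = 0.20
    C_RNA: float = 0.17
    tau_NS: float = 3.2  # min
    tau_RNA: float = 26.0  # min
    acq_bleach_rate: float = 0.0  # min^-1
    koff: float = 0.0  # min^-1
    t_points: Sequence[float] = field(default_factory=lambda: tuple(np.linspace(0.0, 55.0, 12)))
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("frap", "photoconversion"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        for name in ("F_IM", "C_NS", "C_RNA"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.tau_NS <= 0 or self.tau_RNA <= 0:
            raise ParameterError("half-times must be > 0")
        if self.acq_bleach_rate < 0 or self.koff < 0:
            raise ParameterError("decay rates must be >= 0")
        if len(self.t_points) == 0:
            raise ParameterError("t_points must not be empty")
        total = self.F_IM + self.C_NS + self.C_RNA
        if self.mode == "photoconversion" and not np.isclose(total, 1.0, atol=1e-6):
            raise ParameterError(
                f"photoconversion fractions must sum to 1 at t=0, got {total}")
        if self.mode == "frap" and total > 1.0 + 1e-9:
            raise ParameterError(f"FRAP fractions must sum to <= 1, got {total}")


@dataclass
class ImageSimParams:
    """Parameters of the synthetic STED spot-image generator.

    Defaults emulate the imaging geometry used for RNA particles
    (14.6 nm pixels) with ~110 nm Lorentzian spots on a weak noisy
    background (worst-case amplitude/noise ratio 20).
    """

    shape: tuple[int, int] = (768, 768)  # (H, W) px
    pixel_size: float = 14.6  # nm
    n_spots: int = 200
    fwhm_mean: float = 112.0  # nm
    fwhm_sd: float = 10.0  # nm
    amplitude_range: tuple[float, float] = (20.0, 60.0)  # a.u.
    axis_ratio_sd: float = 0.08  # s.d. of log per-axis FWHM ratio
    background_level: float = 5.0  # a.u.
    background_gradient: float = 0.0  # a.u. per px along x
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    noise_scale: float = 1.0
    cluster_fraction: float = 0.0
    cluster_spacing: float = 300.0  # nm, distance to cluster partner
    min_separation: float = 400.0  # nm, between non-clustered spot centres
    margin_px: int = 14
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.fwhm_mean <= 2 * self.pixel_size:
            raise ParameterError("fwhm_mean must exceed 2 pixels to be resolvable")
        _check_prob("cluster_fraction", self.cluster_fraction)
        if self.n_spots < 0:
            raise ParameterError("n_spots must be >= 0")
        h, w = self.shape
        if h <= 2 * self.margin_px or w <= 2 * self.margin_px:
            raise ParameterError("image too small for the requested margin")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, low: float = 0.0) -> np.ndarray:
    """Normal draws resampled until all exceed ``low`` (positive scales)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= low
    return out


def simulate_tracks(params: TrackSimParams,
                    axis: AnteriorAxis = AnteriorAxis()) -> tuple[list[Track], pd.DataFrame]:
    """Generate particle tracks with a controlled anterior direction bias.

    Each track receives one direction: the anterior or posterior
    hemicircle is chosen by ``Bernoulli(anterior_bias)`` and the angle is
    jittered by a zero-mean normal (s.d. ``lateral_spread`` degrees)
    truncated to the hemicircle, so the expected fraction of tracks whose
    net displacement has a positive anterior component equals
    ``anterior_bias``.  Speed is drawn once per track; rare per-frame
    reversals flip the direction of travel for the remainder of the run.

    Returns the tracks and a ground-truth table with one row per track.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ant = axis.anterior_unit
    ant_angle = np.arctan2(ant[1], ant[0])
    post_unit = np.asarray(axis.posterior_unit, dtype=float)
    lat_unit = np.array([-post_unit[1], post_unit[0]])
    origin = np.asarray(axis.origin, dtype=float)

    n = params.n_tracks
    is_anterior = rng.random(n) < params.anterior_bias
    jitter_sd = np.deg2rad(params.lateral_spread)
    if jitter_sd == 0:
        jitter = np.zeros(n)
    else:
        jitter = rng.normal(0.0, jitter_sd, n)
        bad = np.abs(jitter) >= np.pi / 2  # keep direction inside its hemicircle
        while np.any(bad):
            jitter[bad] = rng.normal(0.0, jitter_sd, int(bad.sum()))
            bad = np.abs(jitter) >= np.pi / 2
    angles = np.where(is_anterior, ant_angle, ant_angle + np.pi) + jitter
    speeds = _truncated_normal(rng, params.speed_mean, params.speed_sd, n)
    mobile = rng.random(n) < params.mobile_prob
    lo, hi = params.n_frames_range
    n_frames = rng.integers(lo, hi + 1, n)
    depth = rng.uniform(0.0, params.start_depth_um, n)
    lateral = rng.uniform(-params.start_depth_um / 2, params.start_depth_um / 2, n)

    tracks: list[Track] = []
    truth_rows = []
    for i in range(n):
        m = int(n_frames[i])
        t = np.arange(m) * params.frame_interval
        start = origin + depth[i] * post_unit + lateral[i] * lat_unit
        direction = np.array([np.cos(angles[i]), np.sin(angles[i])])
        sign = np.ones(m - 1)
        flips = rng.random(m - 1) < params.reversal_prob
        cur = 1.0
        for j in range(m - 1):
            if flips[j]:
                cur = -cur
            sign[j] = cur
        step_speed = speeds[i] if mobile[i] else 0.0
        steps = direction[None, :] * (sign * step_speed * params.frame_interval)[:, None]
        pos = start[None, :] + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(0.0, params.position_noise_sd, pos.shape)
        tid = f"track{i:05d}"
        # group labels spread over a plausible design: 3 movies per oocyte
        oocyte = f"oocyte{i % 5}"
        movie = f"movie{i % 15}"
        tracks.append(Track(track_id=tid, t=t, x=pos[:, 0], y=pos[:, 1],
                            oocyte_id=oocyte, movie_id=movie))
        truth_rows.append(dict(
            track_id=tid, hemicircle="anterior" if is_anterior[i] else "posterior",
            direction_angle_rad=float(angles[i]), speed=float(speeds[i]),
            mobile=bool(mobile[i]), n_frames=m,
            n_reversal_events=int(flips.sum()),
            start_distance_um=float(depth[i])))
    return tracks, pd.DataFrame(truth_rows)


def recovery_curve(params: RecoverySimParams, t: np.ndarray) -> np.ndarray:
    """Noiseless measured intensity at times ``t`` (min) under the forward model."""
    t = np.asarray(t, dtype=float)
    ns = params.C_NS * np.exp(-_LN2 * t / params.tau_NS)
    rna_mob = params.C_RNA * np.exp(-_LN2 * t / params.tau_RNA)
    if params.mode == "photoconversion":
        rna = (params.F_IM + rna_mob) * np.exp(-params.koff * t)
        clean = rna + ns
    else:
        # recovering signal; MCP dissociation is negligible over a FRAP
        # recovery of freshly exchanged molecules and is not modelled here
        clean = 1.0 - params.F_IM - ns - rna_mob
    return clean * np.exp(-params.acq_bleach_rate * t)


def simulate_recovery(params: RecoverySimParams) -> IntensitySeries:
    """Simulate one ROI intensity time course (background already subtracted)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.t_points, dtype=float)
    I = recovery_curve(params, t)
    if params.noise_sd > 0:
        I = I + rng.normal(0.0, params.noise_sd, t.shape)
    return IntensitySeries(t=t, I=I, kind=params.mode)


def lorentzian_spot(shape: tuple[int, int], x0: float, y0: float,
                    gamma_x: float, gamma_y: float, amplitude: float) -> np.ndarray:
    """Render one spot as the separable product of per-axis Lorentzians."""
    h, w = shape
    lx = 1.0 / (1.0 + ((np.arange(w) - x0) / gamma_x) ** 2)
    ly = 1.0 / (1.0 + ((np.arange(h) - y0) / gamma_y) ** 2)
    return amplitude * np.outer(ly, lx)


def _place_centres(rng: np.random.Generator, params: ImageSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement honouring margin, minimum separation and clusters."""
    h, w = params.shape
    margin = params.margin_px
    min_sep_px = params.min_separation / params.pixel_size
    capacity = ((h - 2 * margin) * (w - 2 * margin)) / max(np.pi * (min_sep_px / 2) ** 2, 1.0)
    if params.n_spots > 0.7 * capacity:
        raise ParameterError(
            f"{params.n_spots} spots exceed image capacity (~{int(0.7 * capacity)}) "
            f"at min_separation {params.min_separation} nm")
    n_cluster = int(round(params.cluster_fraction * params.n_spots))
    n_seed = params.n_spots - n_cluster
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n_seed:
        tries += 1
        if tries > 200 * max(params.n_spots, 1):
            raise ParameterError("could not place spots at the requested density")
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep_px ** 2 for cx, cy in centres):
            centres.append((x, y))
    clustered = np.zeros(params.n_spots, dtype=bool)
    spacing_px = params.cluster_spacing / params.pixel_size
    for k in range(n_cluster):
        for _ in range(1000):
            px, py = centres[int(rng.integers(0, max(n_seed, 1)))]
            theta = rng.uniform(0, 2 * np.pi)
            x = px + spacing_px * np.cos(theta)
            y = py + spacing_px * np.sin(theta)
            if margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin:
                centres.append((x, y))
                clustered[n_seed + k] = True
                break
        else:
            raise ParameterError("could not place clustered spots inside margins")
    arr = np.asarray(centres, dtype=float)
    return arr, clustered


def _apply_noise(rng: np.random.Generator, image: np.ndarray,
                 params: ImageSimParams) -> np.ndarray:
    if params.noise_model == "gaussian":
        if params.noise_scale > 0:
            image = image + rng.normal(0.0, params.noise_scale, image.shape)
        return image
    # Poisson: interpret noise_scale as counts per intensity unit
    scale = params.noise_scale if params.noise_scale > 0 else 1.0
    return rng.poisson(np.clip(image, 0, None) * scale).astype(float) / scale


def _render(params: ImageSimParams, rng: np.random.Generator,
            centres: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    h, w = params.shape
    n = len(centres)
    fwhm = _truncated_normal(rng, params.fwhm_mean, params.fwhm_sd, n,
                             low=2 * params.pixel_size)
    log_ratio = rng.normal(0.0, params.axis_ratio_sd, n)
    fwhm_x = fwhm * np.exp(log_ratio / 2)
    fwhm_y = fwhm * np.exp(-log_ratio / 2)
    amp = rng.uniform(*params.amplitude_range, n)
    clean = np.zeros((h, w))
    rows = []
    for i in range(n):
        gx = fwhm_x[i] / (2 * params.pixel_size)
        gy = fwhm_y[i] / (2 * params.pixel_size)
        clean += lorentzian_spot((h, w), centres[i, 0], centres[i, 1], gx, gy, amp[i])
        rows.append(dict(spot_id=i, x0=centres[i, 0], y0=centres[i, 1],
                         fwhm_x_nm=fwhm_x[i], fwhm_y_nm=fwhm_y[i],
                         fwhm_nm=(fwhm_x[i] + fwhm_y[i]) / 2, amplitude=amp[i]))
    bg = params.background_level + params.background_gradient * np.arange(w)[None, :]
    return clean + bg, pd.DataFrame(rows, columns=[
        "spot_id", "x0", "y0", "fwhm_x_nm", "fwhm_y_nm", "fwhm_nm", "amplitude"])


def simulate_sted_image(params: ImageSimParams) -> tuple[StedImage, pd.DataFrame]:
    """Generate a spot image plus a ground-truth table (one row per spot).

    Spots are separable 2-D Lorentzians so that the per-axis 1-D profile
    fits used for sizing are exactly invertible.  Background and noise
    are applied after all spots are composited.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    if params.n_spots == 0:
        h, w = params.shape
        bg = params.background_level + params.background_gradient * np.arange(w)[None, :]
        img = _apply_noise(rng, np.broadcast_to(bg, (h, w)).copy(), params)
        return StedImage(pixels=img, pixel_size=params.pixel_size), pd.DataFrame(
            columns=["spot_id", "x0", "y0", "fwhm_x_nm", "fwhm_y_nm", "fwhm_nm", "amplitude"])
    centres, clustered = _place_centres(rng, params)
    image, truth = _render(params, rng, centres)
    truth["clustered"] = clustered
    image = _apply_noise(rng, image, params)
    return StedImage(pixels=image, pixel_size=params.pixel_size), truth


def simulate_two_channel(params: ImageSimParams, coloc_fraction: float,
                         shift_px: int = 0,
                         axis: Literal["x", "y"] = "x") -> tuple[StedImage, StedImage, pd.DataFrame]:
    """Generate a two-channel image pair with a controlled colocalised fraction.

    ``coloc_fraction`` of the channel-2 spots sit at channel-1 positions
    displaced by ``shift_px`` along ``axis``; the remainder are placed
    independently.  Channel-2 sizes and amplitudes are redrawn (a second
    fluorophore need not match the first).
    """
    params.validate()
    _check_prob("coloc_fraction", coloc_fraction)
    if abs(shift_px) >= params.shape[1] // 4:
        raise ParameterError("|shift_px| must be < image width / 4")
    rng = np.random.default_rng(params.seed)
    centres1, clustered1 = _place_centres(rng, params)
    img1, truth1 = _render(params, rng, centres1)
    img1 = _apply_noise(rng, img1, params)

    n = params.n_spots
    n_coloc = int(round(coloc_fraction * n))
    idx = rng.permutation(n)[:n_coloc]
    delta = np.array([shift_px, 0.0]) if axis == "x" else np.array([0.0, shift_px])
    coloc_centres = centres1[idx] + delta[None, :]
    h, w = params.shape
    margin = params.margin_px
    keep = ((coloc_centres[:, 0] >= margin) & (coloc_centres[:, 0] <= w - 1 - margin)
            & (coloc_centres[:, 1] >= margin) & (coloc_centres[:, 1] <= h - 1 - margin))
    coloc_centres = coloc_centres[keep]
    indep = ImageSimParams(**{**params.__dict__, "n_spots": n - len(coloc_centres),
                              "seed": params.seed + 1})
    if indep.n_spots > 0:
        centres2_indep, _ = _place_centres(np.random.default_rng(indep.seed), indep)
        centres2 = np.vstack([coloc_centres, centres2_indep])
    else:
        centres2 = coloc_centres
    img2, truth2 = _render(params, rng, centres2)
    img2 = _apply_noise(rng, img2, params)

    truth1["channel"] = 1
    truth2["channel"] = 2
    truth2["colocalized"] = np.arange(len(centres2)) < len(coloc_centres)
    truth1["colocalized"] = False
    truth1.loc[truth1.index[idx[keep]], "colocalized"] = True
    truth = pd.concat([truth1, truth2], ignore_index=True)
    return (StedImage(pixels=img1, pixel_size=params.pixel_size),
            StedImage(pixels=img2, pixel_size=params.pixel_size), truth)
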