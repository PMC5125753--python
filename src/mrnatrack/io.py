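"""Readers and writers for the package's on-disk formats.

Tracks and intensity series travel as tidy CSV; images as single- or
multi-page grayscale TIFF with the physical pixel size recorded in a
YAML sidecar (``<image>.yaml``) or passed explicitly.  Writing then
reading reproduces values to full precision.  Times are seconds for
tracks and minutes for kinetics; unit conversion happens only at
ingest, never downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import AnteriorAxis, IntensitySeries, ParameterError, StedImage, Track

__all__ = [
    "TRACK_COLUMNS",
    "INTENSITY_COLUMNS",
    "read_tracks",
    "write_tracks",
    "read_intensity",
    "write_intensity",
    "read_image",
    "write_image",
    "read_axis",
    "write_results",
    "write_manifest",
]

TRACK_COLUMNS = ["track_id", "oocyte_id", "movie_id", "frame", "t_s", "x_um", "y_um"]
INTENSITY_COLUMNS = ["t_min", "intensity", "background", "sample_id", "kind"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing columns {missing}")


def read_tracks(path) -> list[Track]:
    """Read a track table; columns are matched by header, not position."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACK_COLUMNS, path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            rows = grp.index[np.where(np.diff(t) <= 0)[0] + 1] + 2  # 1-based + header
            raise ParameterError(
                f"{path}: non-monotone time in track {tid!r} (csv line {rows[0]})")
        tracks.append(Track(
            track_id=str(tid), t=t,
            x=grp["x_um"].to_numpy(dtype=float), y=grp["y_um"].to_numpy(dtype=float),
            oocyte_id=str(grp["oocyte_id"].iloc[0]), movie_id=str(grp["movie_id"].iloc[0]),
            genotype=("" if "genotype" not in grp or pd.isna(grp["genotype"].iloc[0])
                      else str(grp["genotype"].iloc[0]))))
    if not tracks:
        raise ParameterError(f"{path}: no tracks found")
    return tracks


def write_tracks(tracks: Sequence[Track], path) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            rows.append(dict(track_id=tr.track_id, oocyte_id=tr.oocyte_id,
                             movie_id=tr.movie_id, frame=i, t_s=tr.t[i],
                             x_um=tr.x[i], y_um=tr.y[i], genotype=tr.genotype))
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_intensity(path) -> list[IntensitySeries]:
    """Read ROI intensity series; background is subtracted at ingest."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_min", "intensity"], path)
    if "background" not in df.columns:
        df["background"] = 0.0
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample0"
    if "kind" not in df.columns:
        df["kind"] = "frap"
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("t_min")
        out.append(IntensitySeries(
            t=grp["t_min"].to_numpy(dtype=float),
            I=(grp["intensity"] - grp["background"]).to_numpy(dtype=float),
            kind=str(grp["kind"].iloc[0]), sample_id=str(sid)))
    if not out:
        raise ParameterError(f"{path}: no intensity series found")
    return out


def write_intensity(series_list: Sequence[IntensitySeries], path,
                    background: float = 0.0) -> None:
    rows = []
    for s in series_list:
        for t, i in zip(s.t, s.I):
            rows.append(dict(t_min=t, intensity=i + background, background=background,
                             sample_id=s.sample_id, kind=s.kind))
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".yaml")


def read_image(path, pixel_size: Optional[float] = None,
               page: int = 0) -> StedImage:
    """Read one channel of a grayscale TIFF.

    The pixel size (nm) must come from the ``pixel_size`` argument or a
    ``<image>.yaml`` sidecar with a ``pixel_size_nm`` key.
    """
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[page]
    if pixel_size is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            pixel_size = meta.get("pixel_size_nm")
        if pixel_size is None:
            raise ParameterError(
                f"{path}: pixel size not given; pass pixel_size= or provide "
                f"'pixel_size_nm' in {sidecar.name}")
    if pixel_size <= 0:
        raise ParameterError(f"{path}: pixel size must be > 0, got {pixel_size}")
    return StedImage(pixels=np.asarray(data, dtype=float), pixel_size=float(pixel_size))


def write_image(image: StedImage, path, channels: Optional[Sequence[np.ndarray]] = None) -> None:
    """Write a 32-bit TIFF (multi-channel as pages) plus a pixel-size sidecar."""
    if channels is not None:
        stack = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
        tifffile.imwrite(path, stack)
    else:
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    _sidecar_path(path).write_text(
        yaml.safe_dump({"pixel_size_nm": float(image.pixel_size)}))


def read_axis(path) -> AnteriorAxis:
    """Read an anterior-axis definition from YAML (origin + posterior unit vector)."""
    meta = yaml.safe_load(Path(path).read_text())
    try:
        origin = tuple(float(v) for v in meta["origin"])
        unit = np.asarray(meta["posterior_unit"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"{path}: axis file needs 'origin' and 'posterior_unit'") from exc
    unit = unit / np.hypot(*unit)
    return AnteriorAxis(origin=origin, posterior_unit=tuple(unit))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(records, path) -> None:
    """Write result records (dataclasses, dicts or a DataFrame) as JSON or CSV."""
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False)
        return
    path.write_text(json.dumps(_jsonable(records), indent=2) + "\n")


def write_manifest(out_dir, config: dict, seed: Optional[int]) -> None:
    """Record the configuration, seed and library versions of a CLI run."""
    import scipy
    import skimage
    import statsmodels

    from . import __version__

    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "versions": {
            "mrnatrack": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
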