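"""Session-directory I/O.

A session directory holds plain-text tables:

* ``photometry.csv`` — t_s, f465, f405 (demodulated channels)
* ``contacts.csv`` — t_s (lick-port contact times)
* ``pose_profile.csv`` — either the flat dialect
  (frame, jaw_x, jaw_y, jaw_likelihood, tongue_x, tongue_y,
  tongue_likelihood) or the 3-header-row dialect emitted by markerless
  trackers (scorer / bodypart / coordinate); the reader auto-detects.
* ``stim.csv`` — onset_s, width_s
* ``config.yaml`` / ``truth.yaml`` — generator parameters and planted
  ground truth (synthetic sessions only)
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EventSeries, PoseTrack, TimeSeries
from .opto import StimTrain
from .synthetic import CalciumKernel, GeneratorConfig, SessionBundle

__all__ = [
    "write_session",
    "write_dff",
    "read_dff",
    "read_photometry",
    "read_contacts",
    "read_pose",
    "write_pose_tracker_dialect",
    "read_stim",
    "read_truth",
    "read_config",
    "read_annotations",
    "read_acronym_list",
]


def write_session(bundle: SessionBundle, out_dir: str | Path,
                  tracker_dialect: bool = False) -> Path:
    """Serialize a synthetic session bundle to a directory of text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph = bundle.photometry
    pd.DataFrame(
        {"t_s": ph.f465.times, "f465": ph.f465.values, "f405": ph.c405.values}
    ).to_csv(out / "photometry.csv", index=False)
    pd.DataFrame({"t_s": ph.contacts.times_s}).to_csv(out / "contacts.csv", index=False)
    jaw, tongue = bundle.jaw, bundle.tongue
    pd.DataFrame(
        {
            "frame": np.arange(len(jaw)),
            "jaw_x": jaw.x, "jaw_y": jaw.y, "jaw_likelihood": jaw.likelihood,
            "tongue_x": tongue.x, "tongue_y": tongue.y,
            "tongue_likelihood": tongue.likelihood,
        }
    ).to_csv(out / "pose_profile.csv", index=False)
    if tracker_dialect:
        write_pose_tracker_dialect({"jaw": jaw, "tongue": tongue},
                                   out / "pose_profile_tracker.csv")
    if bundle.stim is not None:
        pd.DataFrame(
            {"onset_s": bundle.stim.onsets_s,
             "width_s": np.full(len(bundle.stim), bundle.stim.width_s)}
        ).to_csv(out / "stim.csv", index=False)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(bundle.truth, fh, sort_keys=True)
    cfg = dataclasses.asdict(bundle.config)
    cfg["kernel"] = dataclasses.asdict(bundle.config.kernel)
    if isinstance(cfg.get("bout_structure"), (list, tuple)):
        cfg["bout_structure"] = [[float(s), int(n)] for s, n in cfg["bout_structure"]]
    if math.isinf(cfg["bleach_tau_s"]):
        cfg["bleach_tau_s"] = ".inf"
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out


def read_photometry(session_dir: str | Path) -> tuple[TimeSeries, TimeSeries]:
    """Read photometry.csv; returns (f465, c405).  The rate is inferred
    from the time column, which must be uniform."""
    df = pd.read_csv(Path(session_dir) / "photometry.csv")
    t = df["t_s"].to_numpy()
    if t.size < 2:
        raise ValueError("photometry.csv needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("photometry.csv time grid is not uniform")
    rate = 1.0 / dt[0]
    return (
        TimeSeries(df["f465"].to_numpy(), rate_hz=rate, t0_s=float(t[0])),
        TimeSeries(df["f405"].to_numpy(), rate_hz=rate, t0_s=float(t[0])),
    )


def write_dff(dff, out_dir: str | Path) -> Path:
    """Write dff.csv (t_s, dff) and a provenance sidecar dff_provenance.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_s": dff.times, "dff": dff.values}).to_csv(out / "dff.csv", index=False)
    if dff.provenance:
        prov = {k: (float(v) if isinstance(v, (np.floating, np.integer)) else v)
                for k, v in dff.provenance.items()}
        with open(out / "dff_provenance.yaml", "w") as fh:
            yaml.safe_dump(prov, fh, sort_keys=True)
    return out


def read_dff(session_dir: str | Path):
    from .photometry import DffTrace

    df = pd.read_csv(Path(session_dir) / "dff.csv")
    t = df["t_s"].to_numpy()
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("dff.csv time grid is missing or not uniform")
    return DffTrace(df["dff"].to_numpy(), rate_hz=1.0 / dt[0], t0_s=float(t[0]))


def read_contacts(session_dir: str | Path) -> EventSeries:
    df = pd.read_csv(Path(session_dir) / "contacts.csv")
    return EventSeries(df["t_s"].to_numpy(), kind="contact")


def _read_pose_flat(path: Path, rate_hz: float) -> dict[str, PoseTrack]:
    df = pd.read_csv(path)
    tracks = {}
    for part in ("jaw", "tongue"):
        if f"{part}_y" not in df.columns:
            continue
        tracks[part] = PoseTrack(
            body_part=part,
            x=df[f"{part}_x"].to_numpy(),
            y=df[f"{part}_y"].to_numpy(),
            likelihood=df[f"{part}_likelihood"].to_numpy(),
            rate_hz=rate_hz,
        )
    return tracks


def _read_pose_tracker(path: Path, rate_hz: float) -> dict[str, PoseTrack]:
    # 3-header-row dialect: scorer / bodyparts / coords, index in column 0
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    tracks = {}
    for part in sorted(set(df.columns.get_level_values(1))):
        tracks[part] = PoseTrack(
            body_part=part,
            x=df[(scorer, part, "x")].to_numpy(dtype=float),
            y=df[(scorer, part, "y")].to_numpy(dtype=float),
            likelihood=df[(scorer, part, "likelihood")].to_numpy(dtype=float),
            rate_hz=rate_hz,
        )
    return tracks


def read_pose(session_dir_or_file: str | Path, rate_hz: float = 120.0) -> dict[str, PoseTrack]:
    """Read pose tracks, auto-detecting the flat or 3-header tracker dialect."""
    path = Path(session_dir_or_file)
    if path.is_dir():
        path = path / "pose_profile.csv"
    with open(path) as fh:
        first = fh.readline()
        second = fh.readline()
    if first.lower().startswith("scorer") or second.lower().startswith("bodyparts"):
        return _read_pose_tracker(path, rate_hz)
    return _read_pose_flat(path, rate_hz)


def write_pose_tracker_dialect(tracks: dict[str, PoseTrack], path: str | Path,
                               scorer: str = "synthetic") -> None:
    """Write tracks in the 3-header-row markerless-tracker dialect."""
    cols = {}
    for part, tr in tracks.items():
        cols[(scorer, part, "x")] = tr.x
        cols[(scorer, part, "y")] = tr.y
        cols[(scorer, part, "likelihood")] = tr.likelihood
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    df.to_csv(path, index_label=None)


def read_stim(session_dir: str | Path) -> StimTrain | None:
    path = Path(session_dir) / "stim.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    if df.empty:
        return None
    widths = df["width_s"].to_numpy()
    onsets = df["onset_s"].to_numpy()
    rate = 0.0
    if onsets.size > 1:
        gaps = np.diff(onsets)
        if np.allclose(gaps, gaps[0], rtol=1e-6):
            rate = 1.0 / gaps[0]
    return StimTrain(onsets_s=onsets, width_s=float(widths[0]), rate_hz=rate)


def read_truth(session_dir: str | Path) -> dict:
    with open(Path(session_dir) / "truth.yaml") as fh:
        return yaml.safe_load(fh)


def read_config(session_dir_or_file: str | Path) -> GeneratorConfig:
    path = Path(session_dir_or_file)
    if path.is_dir():
        path = path / "config.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kernel = CalciumKernel(**raw.pop("kernel")) if "kernel" in raw else CalciumKernel()
    if raw.get("bleach_tau_s") == ".inf":
        raw["bleach_tau_s"] = math.inf
    if raw.get("bout_structure") is not None:
        raw["bout_structure"] = [(float(s), int(n)) for s, n in raw["bout_structure"]]
    return GeneratorConfig(kernel=kernel, **raw)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal_id": str, "cell_id": str})


def read_acronym_list(path: str | Path) -> tuple[str, ...]:
    """One acronym per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            out.append(token)
    return tuple(out)
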