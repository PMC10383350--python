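"""File formats and the run manifest.

Formats
-------
* IF cubes: either the portable NumPy ``.npz`` container (lossless complex
  samples) or a raw capture layout -- little-endian interleaved I/Q int16,
  frames-major -- with a JSON sidecar (``<path>.json``) holding the radar
  configuration and the quantization scale.
* Displacement traces: CSV with columns ``time_s, displacement_mm``.
* Cohorts: readings CSV plus a subjects JSON.
* Feature tables: CSV with the documented column names and units
  (ptt_s, pwv_mps, auc_s, sbp_mmhg, dbp_mmhg, pp_mmhg).
* Reports and manifests: JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from .core import DisplacementTrace, IFFrameCube, RadarConfig
from .features import FEATURE_COLUMNS
from .physio import SubjectProfile
from .sim import SyntheticCohort

__all__ = [
    "read_if_cube",
    "write_if_cube",
    "read_trace_csv",
    "write_trace_csv",
    "read_cohort",
    "write_cohort",
    "read_features_csv",
    "write_features_csv",
    "RunManifest",
]

PathLike = Union[str, Path]


def write_if_cube(cube: IFFrameCube, path: PathLike) -> None:
    """Write a cube either as ``.npz`` (lossless) or as raw int16 I/Q.

    The raw layout is frames-major little-endian interleaved I/Q int16; a
    JSON sidecar at ``<path>.json`` records the radar configuration,
    metadata and the float quantization scale. The raw round trip is exact
    at the 16-bit level (idempotent after the first quantization).
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            samples=cube.samples,
            config_json=np.array(cube.config.to_json()),
            dc_offset=np.array([cube.dc_offset]),
            noise_snr_db=np.array([cube.noise_snr_db]),
        )
        return
    peak = float(max(np.abs(cube.samples.real).max(), np.abs(cube.samples.imag).max()))
    scale = peak / 32767.0 if peak > 0 else 1.0
    interleaved = np.empty(cube.samples.size * 2, dtype="<i2")
    interleaved[0::2] = np.round(cube.samples.real.ravel() / scale).astype("<i2")
    interleaved[1::2] = np.round(cube.samples.imag.ravel() / scale).astype("<i2")
    path.write_bytes(interleaved.tobytes())
    sidecar = {
        "format": "raw-iq-int16-le",
        "config": cube.config.to_dict(),
        "scale": scale,
        "dc_offset": [cube.dc_offset.real, cube.dc_offset.imag],
        "noise_snr_db": None if np.isinf(cube.noise_snr_db) else cube.noise_snr_db,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_if_cube(path: PathLike, config: Optional[RadarConfig] = None) -> IFFrameCube:
    """Read a cube written by :func:`write_if_cube`.

    For the raw layout the sample count is validated against the
    configuration (sidecar or explicit ``config``); a truncated or oversized
    file raises a shape-mismatch error naming expected and actual counts.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            cfg = RadarConfig.from_json(str(data["config_json"]))
            if config is not None:
                cfg = config
            return IFFrameCube(
                samples=data["samples"],
                config=cfg,
                dc_offset=complex(data["dc_offset"][0]),
                noise_snr_db=float(data["noise_snr_db"][0]),
            )
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists() and config is None:
        raise FileNotFoundError(f"missing sidecar {sidecar_path} and no config given")
    scale = 1.0
    dc = 0j
    snr = np.inf
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        cfg = RadarConfig.from_dict(meta["config"])
        scale = float(meta.get("scale", 1.0))
        dc_pair = meta.get("dc_offset", [0.0, 0.0])
        dc = complex(dc_pair[0], dc_pair[1])
        snr = np.inf if meta.get("noise_snr_db") is None else float(meta["noise_snr_db"])
    if config is not None:
        cfg = config
    raw = np.frombuffer(path.read_bytes(), dtype="<i2")
    expected = 2 * cfg.n_frames * cfg.adc_samples_per_chirp
    if raw.size != expected:
        raise ValueError(
            f"shape mismatch reading {path}: expected {expected} int16 values "
            f"({cfg.n_frames} frames x {cfg.adc_samples_per_chirp} samples x I/Q), "
            f"found {raw.size}"
        )
    samples = (raw[0::2].astype(float) + 1j * raw[1::2].astype(float)) * scale
    samples = samples.reshape(cfg.n_frames, cfg.adc_samples_per_chirp)
    return IFFrameCube(samples=samples, config=cfg, dc_offset=dc, noise_snr_db=snr)


def write_trace_csv(trace: DisplacementTrace, path: PathLike) -> None:
    df = pd.DataFrame({"time_s": trace.times_s(), "displacement_mm": trace.values_mm})
    df.to_csv(path, index=False)


def read_trace_csv(path: PathLike, radar_id: Optional[str] = None) -> DisplacementTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"trace {path} has fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    return DisplacementTrace(
        values_mm=df["displacement_mm"].to_numpy(dtype=float),
        sample_period_s=dt,
        radar_id=radar_id,
    )


def write_cohort(cohort: SyntheticCohort, readings_path: PathLike, subjects_path: PathLike) -> None:
    cohort.readings.to_csv(readings_path, index=False)
    payload = {
        "rng_seed": cohort.rng_seed,
        "subjects": [s.to_dict() for s in cohort.subjects],
    }
    Path(subjects_path).write_text(json.dumps(payload, indent=2))


def read_cohort(readings_path: PathLike, subjects_path: PathLike) -> SyntheticCohort:
    readings = pd.read_csv(readings_path)
    payload = json.loads(Path(subjects_path).read_text())
    subjects = [SubjectProfile.from_dict(d) for d in payload["subjects"]]
    return SyntheticCohort(subjects=subjects, readings=readings, rng_seed=payload.get("rng_seed"))


def write_features_csv(features: pd.DataFrame, path: PathLike) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    features[FEATURE_COLUMNS].to_csv(path, index=False)


def read_features_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns: {missing}")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one CLI run: config hash, software version,
    per-file checksums and every warning emitted during the run."""

    command: str
    config: dict[str, Any]
    seed: Optional[int] = None
    software_version: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def add_input(self, path: PathLike) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def add_output(self, path: PathLike) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["config_hash"] = self.config_hash
        return d

    def write(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str))
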