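"""On-disk formats: raw int16 I/Q dumps, lossless archives, pipeline config.

The raw dialect mimics an ADC capture dump: little-endian int16, frame-major
then sample-major, I before Q for every sample, with a JSON sidecar
(`<path>.json`) carrying the radar configuration, the quantisation scale and
any ground-truth motion.  For lossless float storage a NumPy ``.npz``
archive embeds the same metadata.  ``PipelineConfig`` is the YAML-backed
bundle of every tunable the CLI needs; unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .config import RadarConfig
from .denoise import WITParams
from .synthetic import ChestMotionModel, ImpairmentModel, IQFrameMatrix
from .vmd import VMDParams

__all__ = [
    "PipelineConfig",
    "write_raw_cube",
    "read_raw_cube",
    "save_cube_npz",
    "load_cube_npz",
]

INT16_FULL_SCALE = 32767


def write_raw_cube(path: str | Path, cube: IQFrameMatrix) -> Path:
    """Write a cube as interleaved little-endian int16 I/Q plus sidecar.

    Samples are scaled so the largest |I| or |Q| maps to full int16 range;
    the scale is recorded in the sidecar for exact de-quantisation.
    """
    path = Path(path)
    data = cube.data  # (n_samples, n_frames)
    peak = float(max(np.abs(data.real).max(), np.abs(data.imag).max()))
    scale = peak / INT16_FULL_SCALE if peak > 0 else 1.0
    # frame-major, then sample-major, I before Q
    frames = data.T  # (n_frames, n_samples)
    inter = np.empty((frames.shape[0], frames.shape[1], 2), dtype="<i2")
    inter[..., 0] = np.round(frames.real / scale)
    inter[..., 1] = np.round(frames.imag / scale)
    path.write_bytes(inter.tobytes())
    sidecar = {
        "config": cube.config.to_dict(),
        "scale": scale,
        "truth": cube.truth.to_dict() if cube.truth is not None else None,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raw_cube(
    path: str | Path, config: RadarConfig | None = None
) -> IQFrameMatrix:
    """Read an interleaved int16 I/Q dump back into a cube.

    The sidecar supplies the configuration and scale when present;
    otherwise ``config`` is required and unit scale is assumed.
    """
    path = Path(path)
    scale = 1.0
    truth = None
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        config = RadarConfig.from_dict(meta["config"])
        scale = float(meta.get("scale", 1.0))
        if meta.get("truth"):
            truth = ChestMotionModel.from_dict(meta["truth"])
    if config is None:
        raise ValueError("no sidecar found: a RadarConfig is required")

    expected = config.n_samples * config.n_frames * 2 * 2  # int16 I and Q
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"raw file size mismatch: expected {expected} bytes for "
            f"{config.n_samples}x{config.n_frames} int16 I/Q, got {actual}"
        )
    raw = np.frombuffer(path.read_bytes(), dtype="<i2").reshape(
        config.n_frames, config.n_samples, 2
    )
    data = (raw[..., 0].astype(float) + 1j * raw[..., 1]) * scale
    return IQFrameMatrix(data=data.T, config=config, truth=truth)


def save_cube_npz(path: str | Path, cube: IQFrameMatrix) -> Path:
    """Lossless float storage: self-describing .npz archive."""
    path = Path(path)
    meta = {
        "config": cube.config.to_dict(),
        "truth": cube.truth.to_dict() if cube.truth is not None else None,
    }
    np.savez_compressed(path, data=cube.data, meta=json.dumps(meta))
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_cube_npz(path: str | Path) -> IQFrameMatrix:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        truth = (
            ChestMotionModel.from_dict(meta["truth"]) if meta["truth"] else None
        )
        return IQFrameMatrix(
            data=z["data"],
            config=RadarConfig.from_dict(meta["config"]),
            truth=truth,
        )


@dataclass
class PipelineConfig:
    """Everything a CLI run needs, round-trippable through YAML."""

    radar: RadarConfig = field(default_factory=RadarConfig)
    motion: ChestMotionModel = field(default_factory=ChestMotionModel)
    impairments: ImpairmentModel = field(default_factory=ImpairmentModel)
    wit: WITParams = field(default_factory=WITParams)
    vmd: VMDParams = field(default_factory=VMDParams)
    conf_threshold: float = 0.4
    diff_threshold: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "radar": self.radar.to_dict(),
            "motion": self.motion.to_dict(),
            "impairments": self.impairments.to_dict(),
            "wit": self.wit.to_dict(),
            "vmd": {
                "K": self.vmd.K,
                "alpha": self.vmd.alpha,
                "tau_admm": self.vmd.tau_admm,
                "eps": self.vmd.eps,
                "max_iter": self.vmd.max_iter,
                "init": self.vmd.init,
            },
            "conf_threshold": self.conf_threshold,
            "diff_threshold": self.diff_threshold,
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, block, converters=()):
            if block is None:
                return klass()
            allowed = {f.name for f in fields(klass)}
            bad = set(block) - allowed
            if bad:
                raise ValueError(
                    f"unknown keys in {klass.__name__}: {sorted(bad)}"
                )
            return (
                klass.from_dict(block)
                if hasattr(klass, "from_dict")
                else klass(**block)
            )

        return cls(
            radar=build(RadarConfig, d.get("radar")),
            motion=build(ChestMotionModel, d.get("motion")),
            impairments=build(ImpairmentModel, d.get("impairments")),
            wit=build(WITParams, d.get("wit")),
            vmd=build(VMDParams, d.get("vmd")),
            conf_threshold=float(d.get("conf_threshold", 0.4)),
            diff_threshold=float(d.get("diff_threshold", 0.1)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
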