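"""In-memory container and HDF5 round-trip for RF channel data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .probe import ProbeConfig

__all__ = ["ChannelData", "save_channel_data", "load_channel_data"]


@dataclass
class ChannelData:
    """Raw or delay-aligned RF channel data.

    ``rf`` is indexed ``[sample, element, scanline]`` where ``element`` runs
    over the walking receive aperture of the corresponding scan line (the
    physical element index is ``first_element[line] + element``).  When
    ``aligned`` is true, the sample axis is a depth axis with geometry given
    by ``depth_grid_mm``.
    """

    rf: np.ndarray
    probe: ProbeConfig
    focus_depth_mm: float
    aligned: bool = False
    depth_grid_mm: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rf.ndim != 3:
            raise ValueError("rf must be (n_samples, n_elements, n_scanlines)")
        if self.rf.shape[1] != self.probe.n_receive:
            raise ValueError(
                f"rf has {self.rf.shape[1]} elements, probe expects "
                f"{self.probe.n_receive}"
            )
        if self.aligned and self.depth_grid_mm is None:
            raise ValueError("aligned data requires a depth grid")

    @property
    def n_samples(self) -> int:
        return self.rf.shape[0]

    @property
    def n_scanlines(self) -> int:
        return self.rf.shape[2]

    def line_x_mm(self) -> np.ndarray:
        return self.probe.scanline_x_mm()[: self.n_scanlines]

    def copy_with(self, **kw) -> "ChannelData":
        return replace(self, **kw)


def save_channel_data(data: ChannelData, path: str | Path) -> None:
    """Write channel data to HDF5 (dataset ``rf``; probe fields as attributes)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("rf", data=data.rf, compression="gzip", compression_opts=1)
        for k, v in vars(data.probe).items():
            ds.attrs[f"probe_{k}"] = -1.0 if v is None else v
        ds.attrs["focus_depth_mm"] = data.focus_depth_mm
        ds.attrs["aligned"] = bool(data.aligned)
        ds.attrs["seed"] = -1 if data.seed is None else int(data.seed)
        if data.depth_grid_mm is not None:
            f.create_dataset("depth_grid_mm", data=data.depth_grid_mm)


def load_channel_data(path: str | Path) -> ChannelData:
    with h5py.File(path, "r") as f:
        ds = f["rf"]
        rf = ds[()]
        pk = {}
        for k, v in ds.attrs.items():
            if k.startswith("probe_"):
                pk[k[len("probe_"):]] = v
        for key in ("n_elements_total", "n_receive", "n_scanlines"):
            pk[key] = int(pk[key])
        sp = float(pk["scanline_pitch_mm"])
        pk["scanline_pitch_mm"] = None if sp < 0 else sp
        for key in ("pitch_mm", "center_frequency_hz", "sampling_frequency_hz",
                    "sound_speed_m_s"):
            pk[key] = float(pk[key])
        probe = ProbeConfig(**pk)
        depth = f["depth_grid_mm"][()] if "depth_grid_mm" in f else None
        seed = int(ds.attrs["seed"])
        return ChannelData(
            rf=rf,
            probe=probe,
            focus_depth_mm=float(ds.attrs["focus_depth_mm"]),
            aligned=bool(ds.attrs["aligned"]),
            depth_grid_mm=depth,
            seed=None if seed < 0 else seed,
        )
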