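"""File formats: signal CSV, feature tables, run configuration, figures.

Signal files are plain-text CSV in one of two dialects:

- two columns ``time_s,value`` (the writer's dialect); the sampling rate
  is inferred from the timestamps, which must be uniform to within 1 us;
- a single ``value`` column with the rate declared in a ``# fs=400``
  header comment.

Header comments (lines starting with ``#``) may also carry ``label=`` and
``id=`` fields, which round-trip through the writer.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import Signal, UNKNOWN, ConfigError
from .wavelet import CWTResult, MOTHER_CONVENTION, PLANES, heatmaps

__all__ = [
    "read_signal",
    "write_signal",
    "read_features",
    "write_features",
    "RunConfig",
    "export_heatmap_pngs",
    "export_coefficients_csv",
]

_TIME_JITTER_TOL = 1e-6  # seconds


def read_signal(path: str | Path) -> Signal:
    """Read a signal CSV; infers fs from timestamps or the header comment."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for m in re.finditer(r"(\w+)=([^\s,]+)", line):
                    header[m.group(1)] = m.group(2)
                continue
            parts = [p for p in re.split(r"[,;\s]+", line) if p]
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                continue  # column-name header line
    if not rows:
        raise ConfigError(f"{path}: no numeric data")
    data = np.asarray(rows, dtype=float)
    label = header.get("label", UNKNOWN)
    sig_id = header.get("id", path.stem)
    if data.shape[1] >= 2:
        t, x = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ConfigError(f"{path}: timestamps must be strictly increasing")
        mean_dt = (t[-1] - t[0]) / (len(t) - 1)
        if np.max(np.abs(dt - mean_dt)) > _TIME_JITTER_TOL:
            raise ConfigError(f"{path}: non-uniform sampling (> 1 us jitter)")
        fs = 1.0 / mean_dt
        # snap to an integral rate when the timestamps round-trip through one
        if abs(fs - round(fs)) < 1e-6 * fs:
            fs = float(round(fs))
    else:
        x = data[:, 0]
        if "fs" not in header:
            raise ConfigError(f"{path}: single-column file needs a '# fs=' header")
        fs = float(header["fs"])
    return Signal(x, fs=fs, label=label, id=sig_id)


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write the two-column ``time_s,value`` dialect (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={signal.fs:g} label={signal.label} id={signal.id}\n")
        fh.write("time_s,value\n")
        for i, v in enumerate(signal.samples):
            fh.write(f"{i / signal.fs:.10g},{float(v):.17g}\n")


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Pipeline parameters; serialised verbatim into every output directory."""

    scale_min: int = 200
    scale_max: int = 1000
    n_scales: int = 64
    spacing: str = "logarithmic"
    n_levels: int = 8
    offset: int = 25
    differentiate: bool = True
    model: str = "random_forest"
    threshold: float = 0.428
    B: int = 200
    seed: int = 0
    wavelet_convention: str = MOTHER_CONVENTION

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def echo(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "run_config.json"
        path.write_text(self.to_json() + "\n")
        return path


def export_coefficients_csv(result: CWTResult, out_dir: str | Path, prefix: str = "cwt") -> list[Path]:
    """Raw interoperability export: one CSV matrix per plane plus the mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    maps = heatmaps(result)
    for name in PLANES:
        p = out / f"{prefix}_{name}.csv"
        np.savetxt(p, maps[name].values, delimiter=",")
        written.append(p)
    p = out / f"{prefix}_mask.csv"
    np.savetxt(p, result.valid_mask.astype(int), fmt="%d", delimiter=",")
    written.append(p)
    p = out / f"{prefix}_scales.csv"
    np.savetxt(p, result.scales, fmt="%d", delimiter=",")
    written.append(p)
    return written


def export_heatmap_pngs(
    result: CWTResult, out_dir: str | Path, prefix: str = "cwt"
) -> list[Path]:
    """Render the four planes as PNGs, masked region in neutral gray,
    scale increasing along the vertical axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    maps = heatmaps(result)
    t_max = result.n / result.fs
    for name in PLANES:
        hm = maps[name]
        masked = np.ma.masked_where(~hm.valid_mask, hm.values)
        fig, ax = plt.subplots(figsize=(8, 4))
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("0.6")
        im = ax.pcolormesh(
            np.linspace(0, t_max, result.n),
            result.scales,
            masked,
            cmap=cmap,
            shading="nearest",
        )
        ax.set_xlabel("time [s]")
        ax.set_ylabel("scale [samples]")
        ax.set_title(f"{name} plane")
        fig.colorbar(im, ax=ax)
        p = out / f"{prefix}_{name}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
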