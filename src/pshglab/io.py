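"""Readers, writers and run configuration.

Stacks travel as multi-page grayscale TIFFs (one page per polarization angle)
with the angle list supplied either by a YAML sidecar (``<stem>.meta.yaml``)
or by an angle-grid specification string like ``"0:170:10"``.  Output maps are
32-bit float TIFFs with NaN marking invalid pixels; summary statistics go to
CSV and a plain-text run report.
"""

from __future__ import annotations

import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidInputError
from .map_analysis import MolecularMaps, SummaryStats
from .pixel_fit import FitMaps, PolarizationStack

__all__ = [
    "RunConfig",
    "parse_angle_spec",
    "read_stack",
    "write_stack",
    "write_phantom",
    "read_phantom_truth",
    "write_outputs",
]


def parse_angle_spec(spec) -> np.ndarray:
    """Angle list from a "start:stop:step" string (stop inclusive) or sequence."""
    if isinstance(spec, str):
        try:
            start, stop, step = (float(x) for x in spec.split(":"))
        except ValueError as exc:
            raise InvalidInputError(f"bad angle spec {spec!r}; expected start:stop:step") from exc
        if step <= 0 or stop < start:
            raise InvalidInputError(f"bad angle spec {spec!r}")
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)
    return np.asarray(list(spec), dtype=float)


@dataclass
class RunConfig:
    """Pipeline configuration; every CLI flag mirrors one field."""

    angles: str = "0:170:10"
    segmentation_threshold: float = 0.2
    smooth_radius: int = 1
    ratio_bin_width: float = 0.01
    angle_bin_width: float = 0.25
    fiber_mask_factor: float = 0.45
    seed: int = 0
    outdir: str = "pshg_out"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.segmentation_threshold <= 1:
            raise InvalidInputError("segmentation_threshold must be in (0, 1]")
        if not 0 < self.fiber_mask_factor <= 1:
            raise InvalidInputError("fiber_mask_factor must be in (0, 1]")
        if self.smooth_radius < 0:
            raise InvalidInputError("smooth_radius must be >= 0")
        parse_angle_spec(self.angles)  # validates

    @property
    def angle_grid(self) -> np.ndarray:
        return parse_angle_spec(self.angles)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix("").with_suffix(".meta.yaml") \
        if stack_path.suffix else stack_path.with_name(stack_path.name + ".meta.yaml")


def read_stack(path, angles_source=None) -> PolarizationStack:
    """Load a polarization stack from a multi-page TIFF or a directory of
    single-page TIFFs in angle order.

    ``angles_source`` is an angle spec / list, or None to read the YAML
    sidecar written by :func:`write_stack`.  Page count must match the angle
    count.
    """
    path = Path(path)
    if path.is_dir():
        pages = [tifffile.imread(p) for p in sorted(path.glob("*.tif*"))]
        if not pages:
            raise InvalidInputError(f"no TIFF files in directory {path}")
        data = np.stack(pages, axis=-1)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise InvalidInputError(f"cannot read TIFF {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        data = np.moveaxis(arr, 0, -1)  # pages-first -> H x W x P

    if angles_source is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise InvalidInputError(f"no angle source given and no sidecar {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        angles = np.asarray(meta["angles"], dtype=float)
    else:
        angles = parse_angle_spec(angles_source)

    if data.shape[-1] != angles.size:
        raise InvalidInputError(
            f"stack has {data.shape[-1]} pages but {angles.size} angles were supplied"
        )
    return PolarizationStack(data=data.astype(float), angles=angles)


def write_stack(stack: PolarizationStack, path, metadata: dict | None = None) -> Path:
    """Write a stack as a multi-page TIFF plus a YAML sidecar with the angles.

    Integer-valued data are stored as uint16 when in range (bit-exact
    round-trip); otherwise float32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(stack.data, -1, 0)
    if np.all(data == np.round(data)) and data.max() < 2**16 and data.min() >= 0:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)
    meta = {"angles": [float(a) for a in stack.angles]}
    if metadata:
        meta.update(metadata)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def write_phantom(phantom, stack: PolarizationStack, path) -> Path:
    """Write a rendered phantom stack with its ground truth alongside.

    The stack goes to ``path`` (+ YAML sidecar including scenario geometry);
    the truth maps (alpha, A, B, C, foreground) go to ``<stem>.truth.tif``.
    """
    path = Path(path)
    geom = asdict(phantom.geometry)
    meta = {"scenario": phantom.geometry.scenario, "geometry": geom,
            "truth_file": path.with_suffix("").name + ".truth.tif"}
    write_stack(stack, path, metadata=meta)
    truth = np.stack(
        [phantom.truth_alpha, phantom.truth_A, phantom.truth_B, phantom.truth_C,
         phantom.foreground.astype(float)]
    ).astype(np.float32)
    tifffile.imwrite(path.with_suffix("").with_suffix(".truth.tif"), truth)
    return path


def read_phantom_truth(stack_path) -> dict:
    """Load the truth maps written by :func:`write_phantom` as a dict of arrays."""
    p = Path(stack_path).with_suffix("").with_suffix(".truth.tif")
    truth = tifffile.imread(p).astype(float)
    names = ["alpha", "A", "B", "C", "foreground"]
    out = {n: truth[i] for i, n in enumerate(names)}
    out["foreground"] = out["foreground"] > 0.5
    return out


_MAP_FILES = {
    "alpha": "alpha_map",
    "chi15": "chi15_map",
    "chi33": "chi33_map",
    "theta": "theta_map",
    "residual": "residual_map",
}


def write_outputs(
    fit: FitMaps,
    mol: MolecularMaps,
    stats: SummaryStats,
    outdir,
    config: RunConfig | None = None,
    fiber_mask: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write all result files for one analyzed stack.

    Produces one float32 TIFF per map (alpha, chi15, chi33, theta, residual;
    NaN = invalid), boolean masks (valid, fiber), ``summary.csv`` with one row
    of :class:`SummaryStats`, and a plain-text run report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    sources = {"alpha": fit.alpha_map, "residual": fit.residual_map,
               "chi15": mol.chi15_map, "chi33": mol.chi33_map, "theta": mol.theta_map}
    for name, arr in sources.items():
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        files[name] = p

    p = outdir / "valid_mask.tif"
    tifffile.imwrite(p, fit.valid_mask.astype(np.uint8))
    files["valid_mask"] = p
    if fiber_mask is not None:
        p = outdir / "fiber_mask.tif"
        tifffile.imwrite(p, np.asarray(fiber_mask).astype(np.uint8))
        files["fiber_mask"] = p

    df = pd.DataFrame([asdict(stats)])
    files["summary"] = outdir / "summary.csv"
    df.to_csv(files["summary"], index=False, float_format="%.12g")

    n_valid = int(fit.valid_mask.sum())
    n_total = int(fit.valid_mask.size)
    lines = [
        "pshglab run report",
        "==================",
        f"python: {platform.python_version()}  numpy: {np.__version__}",
        f"pixels: {n_total}  valid: {n_valid}  invalid: {n_total - n_valid}",
        f"isotropic: {int(fit.isotropic_mask.sum())}",
    ]
    if n_valid == 0:
        lines.append("note: empty valid mask; all maps are NaN sentinels")
    if config is not None:
        lines.append("config:")
        lines += [f"  {k}: {v}" for k, v in asdict(config).items()]
    lines += ["summary:"] + [f"  {k}: {v}" for k, v in asdict(stats).items()]
    files["report"] = outdir / "report.txt"
    files["report"].write_text("\n".join(lines) + "\n")
    return files
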