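"""End-to-end orchestration and file I/O.

The chain is: simulate (or load) a speckle stack -> separate each frame
into envelope and normalized speckle -> extract pairwise overlap values and
displacements -> accumulate, symmetrize and background-subtract the object
autocorrelation -> invert it by phase retrieval -> evaluate.

Frames, autocorrelation grids and reconstructions travel as TIFF (integer
frames, float32 grids) with a JSON sidecar carrying seeds, parameters and,
for simulations, the ground-truth offsets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import assembly, overlap, retrieval, synthetic, trajectory
from .assembly import AutocorrGrid, CoverageError
from .overlap import OverlapRecord
from .retrieval import ModulusField, ReconstructionResult
from .synthetic import ObjectMask, SpeckleStack

__all__ = [
    "RunConfig",
    "PipelineResult",
    "default_cutoff",
    "build_object",
    "simulate",
    "reconstruct_stack",
    "save_stack",
    "load_stack",
    "save_grid",
    "save_reconstruction",
]


def default_cutoff(image_len: int, halo_sigma: float) -> float:
    """Low-pass cutoff (cycles per image) passing a halo of width halo_sigma.

    A Gaussian envelope of spatial sigma ``h`` has spectral sigma
    ``N / (2 pi h)`` cycles per image; 4 spectral sigmas keep essentially
    all envelope energy while rejecting the speckle band.
    """
    return 4.0 * image_len / (2.0 * np.pi * halo_sigma)


@dataclass
class RunConfig:
    """Fully resolved parameters of one simulate/reconstruct run."""

    seed: int = 1
    out_shape: tuple[int, int] = (192, 192)
    grain_size: float = 4.0
    halo_sigma: float = 10.0
    diffuse_fraction: float = 0.5
    n_bands: int = 1
    noise_sigma: float = 0.0
    bit_depth: int | None = None
    object_kind: str = "two_bar"
    object_params: dict = field(default_factory=dict)
    trajectory_shape: str = "U"
    side_length: int = 30
    cutoff: float | None = None  # None -> default_cutoff
    reliability_threshold: float = assembly.RELIABILITY_THRESHOLD
    background: str = "edge_baseline"
    max_pairs: int | None = None
    pr_iters: int = 500
    pr_beta: float = 0.9
    pr_restarts: int = 50
    pr_er_iters: int = 50
    pr_seed: int = 0

    def resolved_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        return default_cutoff(min(self.out_shape), self.halo_sigma)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_shape"] = list(self.out_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "out_shape" in d:
            d["out_shape"] = tuple(d["out_shape"])
        if "object_params" in d and "shape" in d.get("object_params", {}):
            d["object_params"] = dict(d["object_params"])
            d["object_params"]["shape"] = tuple(d["object_params"]["shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_object(config: RunConfig) -> ObjectMask:
    if config.object_kind == "two_bar":
        return synthetic.two_bar_object(**config.object_params)
    if config.object_kind == "point":
        return synthetic.point_object(**config.object_params)
    raise ValueError(f"unknown object_kind {config.object_kind!r}")


def simulate(config: RunConfig):
    """Render the configured speckle sequence.

    Returns ``(stack, medium, obj, path)`` with the trajectory centred so
    the shifted object stays inside the source grid.
    """
    medium = synthetic.make_medium(
        seed=config.seed,
        out_shape=config.out_shape,
        grain_size=config.grain_size,
        halo_sigma=config.halo_sigma,
        diffuse_fraction=config.diffuse_fraction,
        n_bands=config.n_bands,
    )
    obj = build_object(config)
    path = trajectory.make_trajectory(
        config.trajectory_shape, config.side_length
    ).centered()
    stack = synthetic.render_sequence(
        medium,
        obj,
        None,
        path.positions,
        noise_sigma=config.noise_sigma,
        bit_depth=config.bit_depth,
    )
    return stack, medium, obj, path


@dataclass
class PipelineResult:
    """Everything the inverse pipeline produced for one stack."""

    records: list[OverlapRecord]
    grid_raw: AutocorrGrid  # accumulated
    grid_sym: AutocorrGrid  # symmetrized + gap-filled
    grid: AutocorrGrid  # background-subtracted (input to retrieval)
    modulus: ModulusField
    support: tuple[int, int]
    result: ReconstructionResult
    recovered_path: trajectory.TrajectoryPath
    log: dict


def reconstruct_stack(stack: SpeckleStack, config: RunConfig) -> PipelineResult:
    """Run the full inverse chain on a speckle stack."""
    cutoff = config.resolved_cutoff()
    records = overlap.pairwise_overlaps(
        stack, cutoff, max_pairs=config.max_pairs, subsample_seed=config.seed
    )
    reliable = [r for r in records if r.peak_quality >= config.reliability_threshold]
    if not reliable:
        raise ValueError("no reliable pairwise records")
    radius = max(
        max(abs(r.displacement[0]), abs(r.displacement[1])) for r in reliable
    )
    grid_raw = assembly.accumulate(
        records, radius, reliability_threshold=config.reliability_threshold
    )
    grid_sym = assembly.symmetrize(grid_raw)

    # coverage: the recovered path's autocorrelation must cover the strong
    # region of the assembled grid before gaps may be interpolated
    anchor = min(r.i for r in reliable)
    anchor_recs = sorted((r for r in reliable if r.i == anchor), key=lambda r: r.j)
    recovered = trajectory.TrajectoryPath(
        tuple(r.displacement for r in anchor_recs), shape_tag="custom"
    )
    peek = assembly.subtract_background(grid_sym, method="edge_baseline")
    extent = assembly.support_extent(peek.values)
    ok, report = trajectory.check_coverage(recovered, extent)
    if not ok:
        raise CoverageError(
            f"trajectory autocorrelation misses {report['n_missing']} of "
            f"{report['n_required']} required lags within extent {extent}"
        )
    # background first (its outer-annulus baseline must see only genuinely
    # sampled lags), then interpolate the few unsampled gaps for retrieval
    grid_bg = assembly.subtract_background(grid_sym, method=config.background)
    # support box from the unfilled extent: gap-filled corner lags are
    # single-record copies whose noise would stretch the measured extent
    support = (extent[0] + 2, extent[1] + 2)
    grid_bg = assembly.fill_unsampled(grid_bg)
    modulus = retrieval.autocorr_to_modulus(grid_bg)
    result = retrieval.fienup_reconstruct(
        modulus,
        support,
        n_iter=config.pr_iters,
        beta=config.pr_beta,
        restarts=config.pr_restarts,
        seed=config.pr_seed,
        er_iters=config.pr_er_iters,
    )
    log = {
        "n_frames": len(stack),
        "n_records": len(records),
        "n_reliable": len(reliable),
        "cutoff": cutoff,
        "grid_radius": radius,
        "coverage": {k: v for k, v in report.items() if k != "missing_lags"},
        "support_box": list(support),
        "clipped_energy_fraction": modulus.clipped_energy_fraction,
        "pr_residual": result.residual,
        "reliability_threshold": config.reliability_threshold,
        "background": config.background,
    }
    return PipelineResult(
        records=records,
        grid_raw=grid_raw,
        grid_sym=grid_sym,
        grid=grid_bg,
        modulus=modulus,
        support=support,
        result=result,
        recovered_path=recovered,
        log=log,
    )


# ---------------------------------------------------------------------------
# file I/O


def save_stack(
    path: str | Path, stack: SpeckleStack, config: RunConfig | None = None
) -> None:
    """Write a TIFF stack plus a JSON sidecar with truth offsets/parameters."""
    path = Path(path)
    frames = stack.frames
    if stack.bit_depth is not None:
        dtype = np.uint8 if stack.bit_depth <= 8 else np.uint16
        frames = frames.astype(dtype)
    else:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    meta = {
        "bit_depth": stack.bit_depth,
        "truth_offsets": stack.truth_offsets,
        "config": config.to_dict() if config is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_stack(path: str | Path) -> tuple[SpeckleStack, RunConfig | None]:
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    meta_path = path.with_suffix(".json")
    bit_depth = None
    offsets = None
    config = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        bit_depth = meta.get("bit_depth")
        if meta.get("truth_offsets") is not None:
            offsets = [tuple(p) for p in meta["truth_offsets"]]
        if meta.get("config") is not None:
            config = RunConfig.from_dict(meta["config"])
    stack = SpeckleStack(frames=frames, bit_depth=bit_depth, truth_offsets=offsets)
    return stack, config


def save_grid(path: str | Path, grid: AutocorrGrid) -> None:
    path = Path(path)
    tifffile.imwrite(path, grid.values.astype(np.float32))
    tifffile.imwrite(
        path.with_name(path.stem + "_counts.tif"), grid.counts.astype(np.int32)
    )
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "step": grid.step,
                "radius": grid.radius,
                "n_sampled": int(grid.sampled.sum()),
            }
        )
    )


def save_reconstruction(path: str | Path, result: ReconstructionResult) -> None:
    path = Path(path)
    tifffile.imwrite(path, result.image.astype(np.float32))
    img = result.image
    top = img.max()
    preview = (255 * img / top).astype(np.uint8) if top > 0 else img.astype(np.uint8)
    tifffile.imwrite(path.with_name(path.stem + "_preview.tif"), preview)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "residual": result.residual,
                "restarts_used": result.restarts_used,
                "seed": result.seed,
            }
        )
    )
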