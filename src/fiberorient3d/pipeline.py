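"""End-to-end orchestration over arbitrarily large volumes.

The volume is processed in fixed-memory chunks: near-cubic cores tile
the volume exactly once, each read with a margin of ceil(4 sigma_max)
voxels so that smoothing never sees a chunk seam (volume borders are
reflected, matching the whole-volume filter). By default the
structureness sensitivity gamma and the Li/Yen thresholds adapt per
chunk, mirroring the streaming design of the original workflow; the
``global_normalization`` option runs a first pass to fix per-scale
gammas and thresholds volume-wide, which makes chunked output on chunk
cores identical to a whole-volume run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import frangi3d, masking, odf, preprocess
from .volume import VolumeImage, read_volume, write_volume

logger = logging.getLogger(__name__)


@dataclass
class ChunkPlan:
    """Partition of a volume into margin-extended processing chunks.

    ``cores`` tile the volume exactly once (no gaps, no double-writes);
    ``margin`` is the per-side halo, at least ceil(4 sigma_max) voxels.
    """

    shape: tuple[int, int, int]
    cores: list[tuple[slice, slice, slice]]
    margin: int
    core_shape: tuple[int, int, int]

    @property
    def n_chunks(self) -> int:
        return len(self.cores)


def plan_chunks(shape: Sequence[int], voxel_size_um: float,
                chunk_mb: float, sigma_max_um: float) -> ChunkPlan:
    """Near-cubic cores sized so one margin-extended float32 chunk fits
    the ``chunk_mb`` budget; deterministic z-y-x iteration order."""
    shape = tuple(int(s) for s in shape)
    margin = int(np.ceil(4.0 * sigma_max_um / voxel_size_um))
    budget_vox = chunk_mb * 2**20 / 4.0
    core = int(np.floor(budget_vox ** (1.0 / 3.0))) - 2 * margin
    if core < 1:
        raise ValueError(
            f"chunk budget {chunk_mb} MB cannot hold a single voxel core "
            f"plus the 2x{margin}-voxel margin")
    core_shape = tuple(min(core, s) for s in shape)
    starts = [range(0, s, c) for s, c in zip(shape, core_shape)]
    cores = [(slice(z, min(z + core_shape[0], shape[0])),
              slice(y, min(y + core_shape[1], shape[1])),
              slice(x, min(x + core_shape[2], shape[2])))
             for z in starts[0] for y in starts[1] for x in starts[2]]
    return ChunkPlan(shape, cores, margin, core_shape)


def _read_extended(data: np.ndarray, core: tuple[slice, slice, slice],
                   margin: int) -> tuple[np.ndarray, tuple[slice, ...]]:
    """Extract a core plus margin, reflecting (half-sample symmetric,
    like the filter's own border mode) where the volume ends; returns
    the block and the core's slices within it."""
    lo = [max(0, s.start - margin) for s in core]
    hi = [min(n, s.stop + margin) for s, n in zip(core, data.shape)]
    block = data[tuple(slice(a, b) for a, b in zip(lo, hi))]
    pad = [(margin - (s.start - a), margin - (b - s.stop))
           for s, a, b in zip(core, lo, hi)]
    if any(p != (0, 0) for p in pad):
        block = np.pad(block, pad, mode="symmetric")
    inner = tuple(slice(margin, margin + (s.stop - s.start)) for s in core)
    return np.ascontiguousarray(block), inner


@dataclass
class PipelineConfig:
    """Validated settings of one processing run (mirrors the CLI)."""

    fiber_path: str
    soma_path: str | None = None
    output_dir: str = "fiberorient3d_run"
    scales_um: tuple[float, ...] = (1.25,)
    alpha: float = frangi3d.DEFAULT_ALPHA
    beta: float = frangi3d.DEFAULT_BETA
    sv_size_um: float = 16.0
    chunk_mb: float = 50.0
    psf_fwhm_um: tuple[float, float, float] = preprocess.DEFAULT_PSF_FWHM_UM
    blur: bool = True
    resample: bool = True
    soma_rejection: bool = True
    global_normalization: bool = False
    target_um: float = 1.0
    voxel_size_um: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.scales_um = tuple(sorted(float(s) for s in self.scales_um))
        if not self.scales_um or min(self.scales_um) <= 0:
            raise ValueError("scales must be a non-empty positive list")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.sv_size_um <= 0 or self.chunk_mb <= 0 or self.target_um <= 0:
            raise ValueError("sv_size_um, chunk_mb and target_um must be "
                             "positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("scales_um", "psf_fwhm_um", "voxel_size_um"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("scales_um", "psf_fwhm_um", "voxel_size_um"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PipelineOutputs:
    vesselness: np.ndarray
    orientation: np.ndarray
    scale_index: np.ndarray
    masks: masking.MaskSet
    odf_field: odf.ODFField
    plan: ChunkPlan
    paths: dict = field(default_factory=dict)


def _global_gammas(data: np.ndarray, plan: ChunkPlan,
                   vol_meta: VolumeImage,
                   scales_um: Sequence[float]) -> list[float]:
    """First pass of the seam-free mode: per-scale gamma from the
    volume-wide maximum structureness."""
    s_max = np.zeros(len(scales_um), dtype=np.float64)
    for core in plan.cores:
        block, inner = _read_extended(data, core, plan.margin)
        vol = VolumeImage(block, vol_meta.voxel_size_um, vol_meta.channel)
        for i, sigma in enumerate(scales_um):
            h = frangi3d.scale_space_hessian(vol, sigma)
            s_max[i] = max(s_max[i], float(h.structureness()[inner].max()))
    return [s / 2.0 if s > 0 else 1.0 for s in s_max]


def run_arrays(fiber: VolumeImage, soma: VolumeImage | None,
               config: PipelineConfig) -> PipelineOutputs:
    """Run the full chunked analysis on in-memory volumes (the array
    core of :func:`run`; see that function for file-based I/O)."""
    psf = preprocess.PSFModel(*config.psf_fwhm_um) if config.blur else None
    fiber = preprocess.preprocess(fiber, psf, config.target_um,
                                  blur=config.blur, resample=config.resample)
    if soma is not None and config.soma_rejection:
        soma = preprocess.preprocess(soma, None, config.target_um,
                                     blur=False, resample=config.resample)
        if soma.shape != fiber.shape:
            raise ValueError(
                f"fiber {fiber.shape} and soma {soma.shape} volumes are "
                "not congruent after preprocessing")
    vs = fiber.voxel_size_um[0]
    plan = plan_chunks(fiber.shape, vs, config.chunk_mb,
                       max(config.scales_um))
    logger.info("processing %s in %d chunk(s), margin %d vox",
                fiber.shape, plan.n_chunks, plan.margin)
    gammas = None
    if config.global_normalization:
        gammas = _global_gammas(fiber.data, plan, fiber, config.scales_um)
        logger.info("global per-scale gammas: %s",
                    [f"{g:.4g}" for g in gammas])
    v_map = np.zeros(fiber.shape, dtype=np.float32)
    orient = np.zeros(fiber.shape + (3,), dtype=np.float32)
    scale_idx = np.full(fiber.shape, -1, dtype=np.int16)
    fiber_mask = np.zeros(fiber.shape, dtype=bool)
    soma_mask = np.zeros(fiber.shape, dtype=bool) if (
        soma is not None and config.soma_rejection) else None
    for k, core in enumerate(plan.cores):
        t0 = time.time()
        block, inner = _read_extended(fiber.data, core, plan.margin)
        vol = VolumeImage(block, fiber.voxel_size_um, fiber.channel)
        res = frangi3d.multiscale_frangi(vol, config.scales_um, config.alpha,
                                         config.beta, gammas=gammas)
        v_map[core] = res.vesselness[inner]
        orient[core] = res.orientation[inner]
        scale_idx[core] = res.scale_index[inner]
        if not config.global_normalization:
            fiber_mask[core] = masking.li_fiber_mask(res.vesselness)[inner]
            if soma_mask is not None:
                soma_block, s_inner = _read_extended(soma.data, core,
                                                     plan.margin)
                ym = masking.yen_soma_mask(soma_block)
                soma_mask[core] = ym[s_inner]
        logger.info("chunk %d/%d done in %.2fs", k + 1, plan.n_chunks,
                    time.time() - t0)
    if config.global_normalization:
        fiber_mask = masking.li_fiber_mask(v_map)
        if soma_mask is not None:
            soma_mask = masking.yen_soma_mask(soma.data)
    masks = masking.MaskSet(fiber_mask, soma_mask)
    result = frangi3d.VesselnessResult(v_map, orient, scale_idx,
                                       config.scales_um,
                                       fiber.voxel_size_um)
    field_ = masking.apply_masks(result, masks)
    odf_field = odf.supervoxel_odfs(field_, config.sv_size_um,
                                    fiber.voxel_size_um)
    return PipelineOutputs(v_map, orient, scale_idx, masks, odf_field, plan)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for blk in iter(lambda: f.read(1 << 20), b""):
            h.update(blk)
    return h.hexdigest()


def run(config: PipelineConfig) -> PipelineOutputs:
    """File-based entry point: read the input volume(s), run the chunked
    analysis, and write all artifacts into one run directory (config
    snapshot, log, maps, masks, ODF file, content hashes)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        fiber = read_volume(config.fiber_path,
                            voxel_size_um=config.voxel_size_um)
        soma = None
        if config.soma_path is not None:
            soma = read_volume(config.soma_path,
                               voxel_size_um=config.voxel_size_um,
                               channel="soma")
        out = run_arrays(fiber, soma, config)
        config.to_yaml(outdir / "config.yaml")
        vs_out = (config.target_um,) * 3 if config.resample \
            else fiber.voxel_size_um
        paths = {}
        paths["vesselness"] = write_volume(
            VolumeImage(out.vesselness, vs_out, "vesselness"),
            outdir / "vesselness.tif")
        import tifffile
        tifffile.imwrite(outdir / "orientation.tif", out.orientation,
                         photometric="minisblack")
        paths["orientation"] = outdir / "orientation.tif"
        tifffile.imwrite(outdir / "scale_index.tif", out.scale_index)
        paths["scale_index"] = outdir / "scale_index.tif"
        tifffile.imwrite(outdir / "fiber_mask.tif",
                         out.masks.fiber_mask.astype(np.uint8) * 255)
        paths["fiber_mask"] = outdir / "fiber_mask.tif"
        if out.masks.soma_mask is not None:
            tifffile.imwrite(outdir / "soma_mask.tif",
                             out.masks.soma_mask.astype(np.uint8) * 255)
            paths["soma_mask"] = outdir / "soma_mask.tif"
        paths["odf"] = odf.write_odf(out.odf_field, outdir / "odf.nii")
        hashes = {name: _sha256(Path(p)) for name, p in paths.items()}
        (outdir / "hashes.json").write_text(json.dumps(hashes, indent=1))
        out.paths = {k: str(v) for k, v in paths.items()}
        logger.info("run complete: %s", outdir)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
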