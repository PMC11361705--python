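"""Ground-truthed synthetic two-channel fluorescence stacks.

This module generates the inputs the quantification modules consume:
3D two-channel image stacks containing cytoplasmic granules that are
labelled either uniformly throughout their volume (streptavidin-like
detection of a biotinylated bait) or preferentially in a peripheral
shell (antibody-like detection restricted to the granule surface),
plus punctate nuclear-rim signal mimicking nuclear pores, diffuse
background, anisotropic Gaussian PSF blur and camera noise.

All stochastic operations are seeded; every rendered emitter is
returned alongside its ground-truth parameters so parameter-recovery
tests can compare estimates against truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

__all__ = [
    "OpticsSpec",
    "GranuleSpec",
    "PoreRingSpec",
    "SceneSpec",
    "ImageStack",
    "GroundTruth",
    "LfqSimSpec",
    "SimulatedCell",
    "render_scene",
    "simulate_granule_experiment",
    "simulate_lfq_table",
]


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Independent RNG stream keyed by seed and string tokens.

    Keying streams by name (rather than draw order) makes renders
    invariant to the order in which channels or cells are processed.
    """
    key = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(key)


@dataclass(frozen=True)
class OpticsSpec:
    """Acquisition geometry and camera model.

    Lengths are in nanometres.  Defaults correspond to a 100x widefield
    objective with a 6.5 um camera pixel (65 nm/px in the sample plane)
    and a 140 nm z-step.
    """

    pixel_size_xy: float = 65.0
    z_step: float = 140.0
    psf_sigma_xy: float = 110.0
    psf_sigma_z: float = 320.0
    background: float = 10.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("psf_sigma_xy", "psf_sigma_z", "background", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GranuleSpec:
    """A spherical granule emitter.

    ``labelling_mode='volume'`` deposits uniform label density inside
    the full sphere; ``'shell'`` restricts it to the peripheral layer
    of thickness ``shell_fraction * radius``.  ``shell_fraction == 1``
    reduces exactly to volume mode.  ``center`` is (z, y, x) in nm.
    """

    center: tuple[float, float, float]
    radius: float
    channel: str
    labelling_mode: str = "volume"
    shell_fraction: float = 1.0
    amplitude: float = 100.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("granule radius must be > 0")
        if self.labelling_mode not in ("volume", "shell"):
            raise ValueError(f"unknown labelling_mode {self.labelling_mode!r}")
        if not (0.0 < self.shell_fraction <= 1.0):
            raise ValueError("shell_fraction must be in (0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def inner_radius(self) -> float:
        if self.labelling_mode == "volume":
            return 0.0
        return self.radius * (1.0 - self.shell_fraction)


@dataclass(frozen=True)
class PoreRingSpec:
    """Punctate emitters evenly spaced on the mid-plane rim of a nucleus.

    ``channel_scale`` maps channel label -> amplitude factor, so the
    same pore geometry can be rendered brightly in one channel and
    dimly (antibody-inaccessible) in another.
    """

    nucleus_center: tuple[float, float, float]
    nucleus_radius: float
    n_pores: int
    pore_amplitude: float = 20000.0
    channel_scale: dict[str, float] = field(default_factory=dict)
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be > 0")
        if self.n_pores < 0:
            raise ValueError("n_pores must be >= 0")

    def pore_positions(self) -> np.ndarray:
        """(n_pores, 3) array of (z, y, x) positions in nm."""
        theta = self.phase + 2.0 * np.pi * np.arange(self.n_pores) / max(self.n_pores, 1)
        cz, cy, cx = self.nucleus_center
        return np.column_stack(
            [
                np.full(self.n_pores, cz),
                cy + self.nucleus_radius * np.sin(theta),
                cx + self.nucleus_radius * np.cos(theta),
            ]
        )


@dataclass(frozen=True)
class SceneSpec:
    """Full generative description of one field of view."""

    shape: tuple[int, int, int] = (48, 256, 256)
    channels: tuple[str, ...] = ("HA", "strep")
    granules: tuple[GranuleSpec, ...] = ()
    pore_rings: tuple[PoreRingSpec, ...] = ()
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "granules", tuple(self.granules))
        object.__setattr__(self, "pore_rings", tuple(self.pore_rings))

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        o = self.optics
        return (
            self.shape[0] * o.z_step,
            self.shape[1] * o.pixel_size_xy,
            self.shape[2] * o.pixel_size_xy,
        )

    def validate(self) -> None:
        ext = self.extent_nm
        for i, g in enumerate(self.granules):
            if g.channel not in self.channels:
                raise ValueError(f"granule {i} references unknown channel {g.channel!r}")
            if not all(0.0 <= c <= e for c, e in zip(g.center, ext)):
                raise ValueError(
                    f"granule {i} (channel {g.channel!r}) centre {g.center} "
                    f"lies outside the physical volume {ext}"
                )
        for i, ring in enumerate(self.pore_rings):
            pos = ring.pore_positions()
            if pos.size and not (
                (pos >= 0).all() and (pos <= np.asarray(ext)).all()
            ):
                raise ValueError(f"pore ring {i} has pores outside the physical volume")


@dataclass
class ImageStack:
    """Per-channel 3D intensity grids with physical calibration."""

    data: np.ndarray  # (n_channels, z, y, x), non-negative
    channels: tuple[str, ...]
    z_step: float
    pixel_size_xy: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, z, y, x) matching channel labels")
        if self.z_step <= 0 or self.pixel_size_xy <= 0:
            raise ValueError("calibration must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None


@dataclass
class GroundTruth:
    """True emitter parameters for a rendered scene."""

    granules: pd.DataFrame  # one row per granule: centre, radius, mode, ...
    pores: pd.DataFrame  # one row per pore punctum
    seed: int


@dataclass
class SimulatedCell:
    replicate: int
    cell: int
    stack: ImageStack
    truth: GroundTruth


# --------------------------------------------------------------------------
# Rendering

def _rasterize_granule(
    grid: np.ndarray, g: GranuleSpec, optics: OpticsSpec, supersample: int
) -> float:
    """Add a granule's label density to ``grid`` (z, y, x) in place.

    Each voxel receives ``amplitude`` times the occupied fraction of the
    voxel, estimated by ``supersample``^3 subvoxel-centre sampling.
    Returns the total deposited intensity.
    """
    voxel = np.array([optics.z_step, optics.pixel_size_xy, optics.pixel_size_xy])
    lo = np.maximum(np.floor((np.array(g.center) - g.radius) / voxel).astype(int), 0)
    hi = np.minimum(
        np.ceil((np.array(g.center) + g.radius) / voxel).astype(int) + 1,
        np.array(grid.shape),
    )
    if np.any(hi <= lo):
        return 0.0

    s = supersample
    offs = (np.arange(s) + 0.5) / s
    axes = []
    for ax in range(3):
        idx = np.arange(lo[ax], hi[ax])
        sub = (idx[:, None] + offs[None, :]).reshape(-1) * voxel[ax] - g.center[ax]
        axes.append(sub)
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    inside = (d2 <= g.radius**2) & (d2 >= g.inner_radius**2)
    nz, ny, nx = hi - lo
    occupancy = (
        inside.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5)).astype(grid.dtype)
    )
    block = g.amplitude * occupancy
    grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += block
    return float(block.sum())


def _deposit_point(grid: np.ndarray, pos_vox: np.ndarray, amplitude: float) -> None:
    """Trilinearly splat a point emitter at fractional voxel position."""
    base = np.floor(pos_vox - 0.5).astype(int)
    frac = (pos_vox - 0.5) - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = base + (dz, dy, dx)
                if np.any(idx < 0) or np.any(idx >= grid.shape):
                    continue
                w = (
                    (frac[0] if dz else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dx else 1 - frac[2])
                )
                grid[tuple(idx)] += amplitude * w


def render_scene(
    scene: SceneSpec,
    *,
    noise: bool = True,
    supersample: int = 5,
    dtype=np.float64,
) -> tuple[ImageStack, GroundTruth]:
    """Render a scene to a noisy image stack plus its ground truth.

    Pipeline per channel: rasterize granule label density (partial-volume
    aware), splat pore punctae, convolve with the separable anisotropic
    Gaussian PSF, add constant background, then (optionally) apply
    Poisson shot noise followed by additive Gaussian read noise.
    Deterministic for a fixed ``scene.seed``.
    """
    scene.validate()
    optics = scene.optics
    voxel = np.array([optics.z_step, optics.pixel_size_xy, optics.pixel_size_xy])
    sigma_vox = (
        optics.psf_sigma_z / optics.z_step,
        optics.psf_sigma_xy / optics.pixel_size_xy,
        optics.psf_sigma_xy / optics.pixel_size_xy,
    )

    data = np.zeros((len(scene.channels),) + tuple(scene.shape), dtype=dtype)
    granule_rows = []
    pore_rows = []
    for ci, label in enumerate(scene.channels):
        grid = data[ci]
        for gi, g in enumerate(scene.granules):
            if g.channel != label:
                continue
            total = _rasterize_granule(grid, g, optics, supersample)
            granule_rows.append(
                {
                    "granule": gi,
                    "channel": label,
                    "z_nm": g.center[0],
                    "y_nm": g.center[1],
                    "x_nm": g.center[2],
                    "radius_nm": g.radius,
                    "labelling_mode": g.labelling_mode,
                    "shell_fraction": g.shell_fraction,
                    "amplitude": g.amplitude,
                    "raster_total": total,
                }
            )
        for ri, ring in enumerate(scene.pore_rings):
            scale = ring.channel_scale.get(label, 1.0)
            for pi, pos in enumerate(ring.pore_positions()):
                _deposit_point(grid, pos / voxel, ring.pore_amplitude * scale)
                if ci == 0:
                    pore_rows.append(
                        {"ring": ri, "pore": pi, "z_nm": pos[0], "y_nm": pos[1], "x_nm": pos[2]}
                    )
        if any(s > 0 for s in sigma_vox):
            ndimage.gaussian_filter(grid, sigma=sigma_vox, output=grid, mode="reflect")
        grid += optics.background
        if noise:
            rng = _substream(scene.seed, "noise", label)
            noisy = rng.poisson(np.maximum(grid, 0.0)).astype(dtype)
            if optics.read_noise_sd > 0:
                noisy += rng.normal(0.0, optics.read_noise_sd, size=grid.shape)
            np.maximum(noisy, 0.0, out=noisy)
            data[ci] = noisy

    stack = ImageStack(
        data=data,
        channels=tuple(scene.channels),
        z_step=optics.z_step,
        pixel_size_xy=optics.pixel_size_xy,
    )
    truth = GroundTruth(
        granules=pd.DataFrame(granule_rows),
        pores=pd.DataFrame(pore_rows),
        seed=scene.seed,
    )
    return stack, truth


# --------------------------------------------------------------------------
# Replicated granule experiment

def simulate_granule_experiment(
    n_replicates: int = 3,
    cells_per_replicate: int = 25,
    *,
    shape: tuple[int, int, int] = (24, 96, 96),
    optics: OpticsSpec | None = None,
    channels: tuple[str, str] = ("HA", "strep"),
    shell_channel: str = "HA",
    radius_nm: float = 500.0,
    shell_fraction: float = 0.25,
    shell_amplitude: float = 120.0,
    volume_amplitude: float = 80.0,
    jitter: bool = True,
    radius_jitter_sd: float = 0.10,
    seed: int = 0,
    noise: bool = True,
    supersample: int = 5,
) -> list[SimulatedCell]:
    """Simulate a replicated two-channel stress-granule experiment.

    Every cell contains one granule rendered on identical geometry in
    both channels: the ``shell_channel`` (antibody-like) uses peripheral
    shell labelling, the other channel (streptavidin-like) uniform
    volume labelling.  Replicate-level multiplicative jitter on the
    granule radius emulates starvation conditions varying between
    biological replicates; per-cell jitter moves the granule off-centre
    and varies its size.  With ``jitter=False`` the geometry is
    identical in every cell of every replicate.
    """
    if n_replicates < 1 or cells_per_replicate < 1:
        raise ValueError("replicate and cell counts must be >= 1")
    if shell_channel not in channels:
        raise ValueError(f"shell_channel {shell_channel!r} not in {channels}")
    optics = optics or OpticsSpec()
    volume_channel = next(c for c in channels if c != shell_channel)

    cells: list[SimulatedCell] = []
    for rep in range(n_replicates):
        rep_rng = _substream(seed, "replicate", str(rep))
        rep_radius_factor = (
            float(np.exp(rep_rng.normal(0.0, radius_jitter_sd))) if jitter else 1.0
        )
        for cell in range(cells_per_replicate):
            cell_rng = _substream(seed, "cell", f"{rep}:{cell}")
            extent = np.array(
                [shape[0] * optics.z_step, shape[1] * optics.pixel_size_xy, shape[2] * optics.pixel_size_xy]
            )
            center = extent / 2.0
            radius = radius_nm * rep_radius_factor
            if jitter:
                center = center + cell_rng.normal(0.0, extent * 0.05)
                radius *= float(np.exp(cell_rng.normal(0.0, radius_jitter_sd / 2)))
            center = np.clip(center, radius, extent - radius)
            granules = (
                GranuleSpec(
                    center=tuple(center),
                    radius=radius,
                    channel=shell_channel,
                    labelling_mode="shell",
                    shell_fraction=shell_fraction,
                    amplitude=shell_amplitude,
                ),
                GranuleSpec(
                    center=tuple(center),
                    radius=radius,
                    channel=volume_channel,
                    labelling_mode="volume",
                    amplitude=volume_amplitude,
                ),
            )
            scene = SceneSpec(
                shape=shape,
                channels=channels,
                granules=granules,
                optics=optics,
                seed=int(_substream(seed, "scene-seed", f"{rep}:{cell}").integers(2**31)),
            )
            stack, truth = render_scene(
                scene, noise=noise, supersample=supersample, dtype=np.float32
            )
            cells.append(SimulatedCell(replicate=rep, cell=cell, stack=stack, truth=truth))
    return cells


# --------------------------------------------------------------------------
# LFQ table simulation

@dataclass(frozen=True)
class LfqSimSpec:
    """Generative model for a label-free quantification intensity table.

    Per protein, a base log2 intensity is drawn from
    Normal(base_mean, base_sd); each replicate observation adds the
    group's true effect (bait groups only) and replicate noise.  A cell
    goes missing with logistic probability decreasing in its log2
    intensity — the missing-not-at-random dropout near the detection
    limit that downshifted-normal imputation assumes.
    """

    n_proteins: int = 300
    group_sizes: dict[str, int] = field(default_factory=lambda: {"bait": 3, "control": 3})
    control_group: str = "control"
    effects: tuple[float, ...] | float = 0.0  # log2 bait - control, per protein (cycled)
    base_mean: float = 25.0
    base_sd: float = 2.0
    replicate_sd: float = 0.3
    dropout_midpoint: float = 22.5  # log2 intensity of 50% missingness; -inf disables
    dropout_slope: float = 1.0  # per log2 unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.control_group not in self.group_sizes:
            raise ValueError(f"control group {self.control_group!r} missing from group_sizes")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have >= 1 replicate")


def simulate_lfq_table(spec: LfqSimSpec) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Draw a raw-scale LFQ table with MNAR dropout.

    Returns ``(table, true_effects, groups)``: the table has one row per
    protein group and one column per sample (missing = NaN, otherwise
    raw-scale intensity), ``true_effects`` the per-protein log2 effect,
    and ``groups`` the sample->group map.
    """
    rng = _substream(spec.seed, "lfq")
    ids = [f"P{i:05d}" for i in range(spec.n_proteins)]
    effects = np.resize(np.atleast_1d(np.asarray(spec.effects, dtype=float)), spec.n_proteins)
    base = rng.normal(spec.base_mean, spec.base_sd, size=spec.n_proteins)

    groups: dict[str, list[str]] = {}
    columns: dict[str, np.ndarray] = {}
    for group, n in spec.group_sizes.items():
        is_control = group == spec.control_group
        samples = [f"{group}_{i + 1}" for i in range(n)]
        groups[group] = samples
        for s in samples:
            log2_x = base + (0.0 if is_control else effects)
            log2_x = log2_x + rng.normal(0.0, spec.replicate_sd, size=spec.n_proteins)
            if np.isneginf(spec.dropout_midpoint):
                p_miss = np.zeros(spec.n_proteins)
            else:
                p_miss = expit(-spec.dropout_slope * (log2_x - spec.dropout_midpoint))
            missing = rng.random(spec.n_proteins) < p_miss
            raw = np.exp2(log2_x)
            raw[missing] = np.nan
            columns[s] = raw

    table = pd.DataFrame(columns, index=pd.Index(ids, name="protein_group"))
    return table, pd.Series(effects, index=table.index, name="true_log2_effect"), groups
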