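"""Synthetic single-nucleus time-lapse rendering.

Renders a simulated :class:`~synieg.circuit_model.Trajectory` into a
three-channel, seven-slice confocal-like stack (axis order T×Z×C×Y×X):

* ``H2B``  — uniform nuclear fill (segmentation marker),
* ``MCP``  — diffuse nuclear background plus one near-diffraction-limited
  3D-Gaussian focus per genomic integration site, whose volume-integrated
  photon count is proportional to that site's instantaneous transcription
  rate ``T_i(t)``,
* ``YFP``  — diffuse nuclear fill proportional to the reporter protein trace.

Expected-photon images are Poisson sampled, Gaussian read noise and a camera
offset are added, and values are clipped to the camera bit depth.  The focus
z-profile is normalized across the 7 slices, so the total expected focus
photon count is independent of the site's axial position.  Rendering is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .circuit_model import KineticParams, Trajectory
from .errors import ValidationError

__all__ = [
    "CellGeometry",
    "OpticsNoise",
    "MovieStack",
    "CHANNEL_ROLES",
    "render_movie",
    "jitter_population",
    "write_tiff",
    "read_tiff",
]

CHANNEL_ROLES = ("H2B", "MCP", "YFP")

Z_STEP_UM = 0.8
N_Z = 7


@dataclass(frozen=True)
class CellGeometry:
    """Single-nucleus scene: ellipse nucleus and transcription-site positions.

    ``site_positions`` are (x_px, y_px, z_um) triples; z is relative to the
    stack center.  Pixel coordinates are 0-based, (row, col) = (y, x).
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.27
    nucleus_center: tuple[float, float] = (64.0, 64.0)   # (y, x) px
    nucleus_semiaxes: tuple[float, float] = (18.0, 22.0)  # (y, x) px
    site_positions: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        ny, nx = self.image_shape
        cy, cx = self.nucleus_center
        ay, ax = self.nucleus_semiaxes
        if ay <= 0 or ax <= 0 or self.pixel_size_um <= 0:
            raise ValidationError("geometry scales must be positive")
        if (cy - ay < 5 or cx - ax < 5 or cy + ay > ny - 5 or cx + ax > nx - 5):
            raise ValidationError("nucleus must fit in the frame with >= 5 px margin")
        z_half = (N_Z - 1) / 2 * Z_STEP_UM
        pos = tuple(tuple(float(v) for v in s) for s in self.site_positions)
        object.__setattr__(self, "site_positions", pos)
        for x, y, z in pos:
            if ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 >= 1.0:
                raise ValidationError(f"site ({x:.1f}, {y:.1f}) outside the nucleus")
            if abs(z) > z_half:
                raise ValidationError(f"site z={z} µm outside the stack span")
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = np.hypot(pos[i][0] - pos[j][0], pos[i][1] - pos[j][1])
                if d < 4.0:
                    raise ValidationError(f"sites {i} and {j} closer than 4 px in-plane")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    def nucleus_mask(self) -> np.ndarray:
        ny, nx = self.image_shape
        cy, cx = self.nucleus_center
        ay, ax = self.nucleus_semiaxes
        yy, xx = np.mgrid[0:ny, 0:nx]
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    @classmethod
    def random(cls, n_sites: int = 8, seed: int = 0, margin_px: float = 7.0,
               z_span_um: float = 1.6, **kwargs) -> "CellGeometry":
        """Sample well-separated site positions inside the nucleus (seeded).

        ``margin_px`` keeps sites away from the nuclear rim so a 9x9 fit
        window around a focus sees uniform nucleoplasmic background.
        """
        proto = cls(**kwargs)
        cy, cx = proto.nucleus_center
        ay, ax = proto.nucleus_semiaxes
        rng = np.random.default_rng(seed)
        pos: list[tuple[float, float, float]] = []
        for _ in range(20000):
            if len(pos) == n_sites:
                break
            u, v = rng.random(2)
            r, th = np.sqrt(u) * 0.9, 2 * np.pi * v
            x = cx + (ax - margin_px) * r * np.cos(th)
            y = cy + (ay - margin_px) * r * np.sin(th)
            if all(np.hypot(x - p[0], y - p[1]) >= 5.0 for p in pos):
                z = rng.uniform(-z_span_um, z_span_um)
                pos.append((float(x), float(y), float(z)))
        if len(pos) < n_sites:
            raise ValidationError(f"could not place {n_sites} separated sites")
        return replace(proto, site_positions=tuple(pos))


@dataclass(frozen=True)
class OpticsNoise:
    """PSF widths, gain, background and camera-noise model for the renderer.

    Gains map model arbitrary units to expected photons; the MCP gain applies
    to the volume-integrated focus signal per site, the YFP gain per pixel of
    nuclear fill.  ``yfp_autofluorescence_au`` defaults to 0 because the
    simulated protein trace already carries a constitutive background term.
    """

    psf_sigma_xy_px: float = 1.3
    psf_sigma_z_um: float = 0.9
    mcp_photons_per_au: float = 10000.0
    yfp_photons_per_au: float = 0.5
    mcp_nuclear_background_au: float = 0.02
    yfp_autofluorescence_au: float = 0.0
    h2b_photons: float = 400.0
    read_noise_sd: float = 3.0
    camera_offset: float = 100.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        for name in ("psf_sigma_xy_px", "psf_sigma_z_um", "mcp_photons_per_au",
                     "yfp_photons_per_au", "mcp_nuclear_background_au",
                     "yfp_autofluorescence_au", "h2b_photons", "read_noise_sd",
                     "camera_offset"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")


@dataclass
class MovieStack:
    """T×Z×C×Y×X intensity stack with calibration and optional ground truth."""

    data: np.ndarray
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    dt_min: float = 2.0
    z_step_um: float = Z_STEP_UM
    pixel_size_um: float = 0.27
    seed: int | None = None
    optics: OpticsNoise | None = None
    ground_truth: tuple[Trajectory, CellGeometry] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValidationError("stack must be T x Z x C x Y x X")
        if self.data.shape[1] != N_Z:
            raise ValidationError(f"expected {N_Z} z-slices, got {self.data.shape[1]}")
        if self.data.shape[2] != len(self.channel_roles):
            raise ValidationError("channel axis does not match channel_roles")
        if np.any(self.data < 0):
            raise ValidationError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_min

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise ValidationError(
                f"no channel with role {role!r}; present: {self.channel_roles}"
            ) from None

    def channel(self, role: str) -> np.ndarray:
        """T×Z×Y×X sub-stack of one channel."""
        return self.data[:, :, self.channel_index(role)]


def _focus_patch(shape, x0, y0, sigma, total):
    """Expected-photon image of one 2D Gaussian focus (small-patch evaluation)."""
    ny, nx = shape
    half = int(np.ceil(5 * sigma))
    x_lo, x_hi = max(0, int(x0) - half), min(nx, int(x0) + half + 1)
    y_lo, y_hi = max(0, int(y0) - half), min(ny, int(y0) + half + 1)
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    g = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2))
    g *= total / (2 * np.pi * sigma ** 2)
    return (slice(y_lo, y_hi), slice(x_lo, x_hi)), g


def render_movie(
    traj: Trajectory,
    geom: CellGeometry,
    optics: OpticsNoise,
    seed: int,
    noise: bool = True,
) -> MovieStack:
    """Render a trajectory into a synthetic stack (deterministic given seed).

    With ``noise=False``, Poisson and read noise are disabled and the stack
    holds rounded expected intensities (for validating the quantification
    chain against ground truth).
    """
    if traj.n_sites != geom.n_sites:
        raise ValidationError(
            f"trajectory has {traj.n_sites} sites but geometry has {geom.n_sites}"
        )
    rng = np.random.default_rng(seed)
    n_t = len(traj.time_grid)
    ny, nx = geom.image_shape
    mask = geom.nucleus_mask()
    z_um = (np.arange(N_Z) - (N_Z - 1) / 2) * Z_STEP_UM

    # per-site normalized axial weights (photon conservation across z)
    weights = np.empty((geom.n_sites, N_Z))
    for i, (_, _, z0) in enumerate(geom.site_positions):
        w = np.exp(-((z_um - z0) ** 2) / (2 * optics.psf_sigma_z_um ** 2))
        weights[i] = w / w.sum()

    max_val = 2 ** optics.bit_depth - 1
    out = np.empty((n_t, N_Z, 3, ny, nx), dtype=np.uint16 if optics.bit_depth == 16 else np.uint8)
    mcp_bg = optics.mcp_nuclear_background_au * optics.mcp_photons_per_au
    saturated = False

    for t_idx in range(n_t):
        expected = np.zeros((N_Z, 3, ny, nx))
        expected[:, 0][:, mask] = optics.h2b_photons
        expected[:, 1][:, mask] = mcp_bg
        yfp_fill = (traj.protein[t_idx] * optics.yfp_photons_per_au
                    + optics.yfp_autofluorescence_au * optics.yfp_photons_per_au)
        expected[:, 2][:, mask] = yfp_fill
        for i, (x0, y0, _) in enumerate(geom.site_positions):
            total = traj.tx_rates[i, t_idx] * optics.mcp_photons_per_au
            if total <= 0:
                continue
            for k in range(N_Z):
                sl, g = _focus_patch((ny, nx), x0, y0, optics.psf_sigma_xy_px,
                                     total * weights[i, k])
                expected[k, 1][sl] += g
        if noise:
            frame = rng.poisson(expected).astype(float)
            frame += rng.normal(0.0, optics.read_noise_sd, size=frame.shape)
            frame += optics.camera_offset
        else:
            frame = expected + optics.camera_offset
        if np.any(expected + optics.camera_offset > max_val):
            saturated = True
        out[t_idx] = np.clip(np.rint(frame), 0, max_val).astype(out.dtype)

    if saturated:
        import logging

        logging.getLogger(__name__).warning(
            "expected intensities exceed the %d-bit range; output saturated",
            optics.bit_depth,
        )
    dt = float(traj.time_grid[1] - traj.time_grid[0]) if n_t > 1 else 1.0
    return MovieStack(
        data=out,
        dt_min=dt,
        pixel_size_um=geom.pixel_size_um,
        seed=seed,
        optics=optics,
        ground_truth=(traj, geom),
    )


# parameters given multiplicative cell-to-cell variability by jitter_population;
# expression amplitudes and turnover vary between cells, while the adaptation
# clock does not (transcription kinetics are near-identical across cells)
JITTERED_PARAMS = ("k_tx", "k_tl", "delta_m0")


def jitter_population(
    base_geom: CellGeometry,
    base_params: KineticParams,
    n_cells: int,
    cv: float,
    seed: int,
) -> list[tuple[CellGeometry, KineticParams]]:
    """n_cells replicates with log-normal parameter jitter and fresh site layouts.

    Each parameter in ``JITTERED_PARAMS`` is multiplied by an independent
    mean-one log-normal factor with coefficient of variation ``cv``.
    """
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    cells = []
    for c in range(n_cells):
        if cv == 0:
            params = base_params
            geom = base_geom
        else:
            factors = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(JITTERED_PARAMS))
            params = base_params.replace(
                **{n: getattr(base_params, n) * f for n, f in zip(JITTERED_PARAMS, factors)}
            )
            geom = CellGeometry.random(
                n_sites=base_geom.n_sites or 8,
                seed=int(rng.integers(2 ** 31)),
                image_shape=base_geom.image_shape,
                pixel_size_um=base_geom.pixel_size_um,
                nucleus_center=base_geom.nucleus_center,
                nucleus_semiaxes=base_geom.nucleus_semiaxes,
            )
        cells.append((geom, params))
    return cells


# ---------------------------------------------------------------------------
# TIFF I/O (TZCYX, metadata in the image description + JSON sidecar)

def write_tiff(path, movie: MovieStack, sidecar: bool = True) -> None:
    import tifffile

    meta = {
        "axes": "TZCYX",
        "channel_roles": list(movie.channel_roles),
        "dt_min": movie.dt_min,
        "z_step_um": movie.z_step_um,
        "pixel_size_um": movie.pixel_size_um,
        "seed": movie.seed,
    }
    tifffile.imwrite(str(path), movie.data, metadata=meta,
                     photometric="minisblack")
    if sidecar:
        side = dict(meta)
        if movie.optics is not None:
            side["optics"] = {k: getattr(movie.optics, k) for k in (
                "psf_sigma_xy_px", "psf_sigma_z_um", "mcp_photons_per_au",
                "yfp_photons_per_au", "mcp_nuclear_background_au",
                "yfp_autofluorescence_au", "h2b_photons", "read_noise_sd",
                "camera_offset", "bit_depth")}
        if movie.ground_truth is not None:
            _, geom = movie.ground_truth
            side["geometry"] = {
                "image_shape": list(geom.image_shape),
                "pixel_size_um": geom.pixel_size_um,
                "nucleus_center": list(geom.nucleus_center),
                "nucleus_semiaxes": list(geom.nucleus_semiaxes),
                "site_positions": [list(s) for s in geom.site_positions],
            }
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh, indent=1)


def read_tiff(path) -> MovieStack:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    kwargs = {}
    geom = None
    try:
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        meta = {**side, **meta}
        if "optics" in side:
            kwargs["optics"] = OpticsNoise(**side["optics"])
        if "geometry" in side:
            g = side["geometry"]
            geom = CellGeometry(
                image_shape=tuple(g["image_shape"]),
                pixel_size_um=g["pixel_size_um"],
                nucleus_center=tuple(g["nucleus_center"]),
                nucleus_semiaxes=tuple(g["nucleus_semiaxes"]),
                site_positions=tuple(tuple(s) for s in g["site_positions"]),
            )
    except FileNotFoundError:
        pass
    if data.ndim == 4:  # single z or single channel written without that axis
        raise ValidationError("stack is not TZCYX; re-export with all five axes")
    movie = MovieStack(
        data=data,
        channel_roles=tuple(meta.get("channel_roles", CHANNEL_ROLES)),
        dt_min=float(meta.get("dt_min", 2.0)),
        z_step_um=float(meta.get("z_step_um", Z_STEP_UM)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.27)),
        seed=meta.get("seed"),
        **kwargs,
    )
    if geom is not None:
        movie.ground_truth = (None, geom)  # trajectory travels separately as CSV
    return movie
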