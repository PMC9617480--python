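"""Synthetic time-lapse generator with exact ground truth.

Renders two-channel nuclear fields that emulate the laser-microirradiation
experiments this package quantifies:

* a **probe** channel (lamin-like): a bright NE rim plus a diffusible
  nucleoplasmic pool, with saturating accumulation at a 2-um rupture ROI on
  the rim after the irradiation frame;
* a **reporter** channel (NLS-like): a nuclear reporter that leaks to the
  cytoplasm through the open rupture until resealing, following a
  two-compartment well-mixed exchange solved in closed form;
* optionally, a FRAP regime: uniform nucleoplasmic signal, a circular bleach
  spot, single-exponential recovery with a mobile fraction.

Kinetic forms are deliberately the simplest that reproduce the plateauing
behaviour of the real traces — single-exponential saturation for
accumulation and recovery, first-order exchange for leakage — so that every
downstream estimator can be checked against known truth. Acquisition
photobleaching multiplies every pixel by ``exp(-beta * frame)``; shot and
read noise are applied last, on the bleached signal, as a detector would see
it. Ground truth always records the noiseless, bleach-free values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import AcquisitionConfig, ImageStack
from .segment import CircleROI, rasterize_circle

__all__ = [
    "SceneGeometry",
    "FrapParams",
    "NoiseParams",
    "SimulationParams",
    "GroundTruth",
    "make_scene",
    "simulate_rupture_timelapse",
    "simulate_frap_timelapse",
    "apply_noise",
    "reporter_leak_solution",
    "default_frap_params",
    "LABEL_BACKGROUND",
    "LABEL_CYTOPLASM",
    "LABEL_NE_RIM",
    "LABEL_NUCLEOPLASM",
]

LABEL_BACKGROUND = 0
LABEL_CYTOPLASM = 1
LABEL_NE_RIM = 2
LABEL_NUCLEOPLASM = 3

#: Fraction of nucleoplasmic-pool signal left after a pre-rupture photobleach.
POOL_BLEACH_RESIDUAL = 0.05
#: Rim enrichment of the assembled (non-pool) probe fraction over its
#: would-be nucleoplasmic concentration; purely a rendering contrast choice.
RIM_ENRICHMENT = 4.0


@dataclass
class SceneGeometry:
    """Static cell geometry: an elliptical nucleus inside an elliptical cell.

    ``pixel_size`` defaults to 69 nm/px so that a 3-pixel erosion depth
    corresponds to 207 nm, matching the imaging convention the analysis
    modules assume.
    """

    image_shape: tuple[int, int] = (192, 192)
    pixel_size: float = 69.0  # nm/px
    nucleus_center: Optional[tuple[float, float]] = None  # (row, col); None = image center
    nucleus_radii: tuple[float, float] = (50.0, 42.0)  # (row, col) semi-axes, px
    cell_radii: tuple[float, float] = (80.0, 72.0)
    rim_width: int = 3

    def center(self) -> tuple[float, float]:
        if self.nucleus_center is not None:
            return self.nucleus_center
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.rim_width < 1:
            raise ConfigurationError("rim_width must be >= 1")
        if not all(n < c for n, c in zip(self.nucleus_radii, self.cell_radii)):
            raise ConfigurationError(
                f"nucleus radii {self.nucleus_radii} must be strictly inside "
                f"cell radii {self.cell_radii}"
            )
        cy, cx = self.center()
        for (ctr, rad, size) in ((cy, self.cell_radii[0], self.image_shape[0]),
                                 (cx, self.cell_radii[1], self.image_shape[1])):
            if ctr - rad <= 0 or ctr + rad >= size - 1:
                raise ConfigurationError("cell boundary must lie strictly inside the image")


@dataclass
class FrapParams:
    """Bleach/recovery settings.

    ``bleach_depth`` is the fraction of pre-bleach intensity *remaining*
    immediately after the bleach (the post-bleach floor); ``mobile_fraction``
    is the fraction of the bleached-away signal that recovers.
    Defaults mirror a point-scan protocol: five pre-bleach frames, a 2-um
    bleach circle, recovery sampled at the acquisition interval.
    """

    bleach_frame: int = 5  # index of the first post-bleach frame; frames 0..4 are pre
    bleach_depth: float = 0.3
    mobile_fraction: float = 0.8
    k_rec: float = 0.1  # 1/s
    spot_diameter: float = 2.0  # um

    def validate(self, n_frames: int) -> None:
        if self.bleach_frame <= 0:
            raise ConfigurationError("bleach_frame must be > 0 (need pre-bleach frames)")
        if self.bleach_frame >= n_frames:
            raise ConfigurationError("bleach_frame beyond the end of the stack")
        for name in ("bleach_depth", "mobile_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.k_rec < 0 or self.spot_diameter <= 0:
            raise ConfigurationError("k_rec must be >= 0 and spot_diameter > 0")


@dataclass
class NoiseParams:
    """Shot + read noise. ``photon_gain`` is detected photons per intensity
    unit (None disables shot noise); ``read_sigma`` is additive Gaussian sigma
    in intensity units."""

    photon_gain: Optional[float] = None
    read_sigma: float = 0.0

    def validate(self) -> None:
        if self.photon_gain is not None and self.photon_gain <= 0:
            raise ConfigurationError("photon_gain must be > 0 when set")
        if self.read_sigma < 0:
            raise ConfigurationError("read_sigma must be >= 0")


@dataclass
class SimulationParams:
    """Generative parameters for one cell.

    Defaults describe an LC-like probe (large nucleoplasmic pool, fast
    accumulation reaching threshold within tens of seconds) imaged at 10-s
    intervals with rupture induced after the first frame.
    """

    frame_interval: float = 10.0  # s
    n_frames: int = 31
    rupture_frame: int = 1  # irradiation happens after the first acquired frame
    amplitude: float = 2.0  # A: saturating fold-increase over site baseline (per unit pool)
    k_acc: float = 0.02  # 1/s accumulation rate
    pool_fraction: float = 0.7  # fraction of probe in the diffusible nucleoplasmic pool
    pool_bleached: bool = False
    leak_conductance: float = 0.01  # g, 1/s
    reseal_time: float = 120.0  # s the rupture stays open
    V_n: float = 1.0
    V_c: float = 3.0
    beta: float = 0.0  # acquisition-bleaching rate, 1/frame
    probe_level: float = 400.0  # probe concentration scale (arbitrary counts)
    reporter_level: float = 800.0  # nuclear reporter concentration at t=0
    reporter_cyto0: float = 0.0  # cytoplasmic reporter concentration at t=0
    background: float = 20.0  # cellular background offset rendered into every pixel
    site_diameter: float = 2.0  # um, irradiation ROI
    frap: Optional[FrapParams] = None
    noise: Optional[NoiseParams] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames")
        if not 0 <= self.rupture_frame < self.n_frames:
            raise ConfigurationError("rupture_frame must lie within the stack")
        if not 0 <= self.pool_fraction <= 1:
            raise ConfigurationError("pool_fraction must be in [0, 1]")
        for name in ("amplitude", "k_acc", "leak_conductance", "reseal_time",
                     "beta", "frame_interval", "probe_level", "reporter_level"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.V_n <= 0 or self.V_c <= 0:
            raise ConfigurationError("compartment volumes must be > 0")
        if self.frap is not None:
            self.frap.validate(self.n_frames)
        if self.noise is not None:
            self.noise.validate()


@dataclass
class GroundTruth:
    """Noiseless, bleach-free per-frame compartment values plus true masks.

    ``traces`` maps compartment name -> per-frame value as rendered (signal
    plus the constant cellular background). Masks are mutually exclusive
    where they are compared against rendered means (the site ROI is carved
    out of the ring/nucleoplasm/cytoplasm truth masks).
    """

    times: np.ndarray
    traces: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    params: SimulationParams
    geometry: SceneGeometry

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, values in self.traces.items():
            for f, (t, v) in enumerate(zip(self.times, values)):
                rows.append({"frame": f, "time_s": t, "compartment": name, "value": v})
        return pd.DataFrame(rows, columns=["frame", "time_s", "compartment", "value"])

    def write(self, out_dir: str | Path, stem: str = "ground_truth") -> None:
        out = Path(out_dir)
        self.to_frame().to_csv(out / f"{stem}.csv", index=False, lineterminator="\n")
        doc = {
            "params": _params_dict(self.params),
            "geometry": asdict(self.geometry),
            "mask_areas_px": {k: int(v.sum()) for k, v in self.masks.items()},
        }
        with open(out / f"{stem}.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _params_dict(params: SimulationParams) -> dict:
    d = asdict(params)
    return d


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return ((rows - center[0]) / radii[0]) ** 2 + ((cols - center[1]) / radii[1]) ** 2 <= 1.0


def make_scene(geometry: SceneGeometry) -> np.ndarray:
    """Render the static label image {background, cytoplasm, NE rim, nucleoplasm}.

    The rim is the band of ``rim_width`` pixels just inside the nucleus
    boundary (nucleus minus its disk-erosion), so the four labels partition
    the image and rim + nucleoplasm exactly tile the nucleus.
    """
    from skimage.morphology import erosion, disk

    geometry.validate()
    center = geometry.center()
    nucleus = _ellipse_mask(geometry.image_shape, center, geometry.nucleus_radii)
    cell = _ellipse_mask(geometry.image_shape, center, geometry.cell_radii)
    inner = erosion(nucleus, disk(geometry.rim_width))
    labels = np.full(geometry.image_shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[cell & ~nucleus] = LABEL_CYTOPLASM
    labels[nucleus & ~inner] = LABEL_NE_RIM
    labels[inner] = LABEL_NUCLEOPLASM
    return labels


def reporter_leak_solution(
    times: np.ndarray,
    t0: float,
    g: float,
    reseal_time: float,
    V_n: float,
    V_c: float,
    n0: float,
    c0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form two-compartment exchange for the NLS reporter.

    ``dn/dt = -(g/V_n)(n - c)``, ``dc/dt = +(g/V_c)(n - c)`` while the
    rupture is open (``t0 <= t <= t0 + reseal_time``), zero flux otherwise.
    Concentrations relax toward the common equilibrium
    ``(V_n n0 + V_c c0) / (V_n + V_c)`` at rate ``g (1/V_n + 1/V_c)``;
    total amount ``V_n n + V_c c`` is conserved exactly.
    """
    times = np.asarray(times, dtype=float)
    lam = g * (1.0 / V_n + 1.0 / V_c)
    tau = np.clip(times - t0, 0.0, reseal_time)
    eq = (V_n * n0 + V_c * c0) / (V_n + V_c)
    decay = np.exp(-lam * tau)
    n = eq + (n0 - eq) * decay
    c = eq + (c0 - eq) * decay
    return n, c


def _site_roi_mask(geometry: SceneGeometry, diameter_um: float) -> np.ndarray:
    """Irradiation ROI: a circle centred on the NE rim at the +x pole."""
    cy, cx = geometry.center()
    roi = CircleROI(
        center=(cy, cx + geometry.nucleus_radii[1]),
        diameter=diameter_um,
        pixel_size=geometry.pixel_size,
    )
    return rasterize_circle(roi, geometry.image_shape)


def _acquisition(geometry: SceneGeometry, params: SimulationParams,
                 event: str, event_frame: int, n_channels: int) -> AcquisitionConfig:
    roles = {0: "probe", 1: "reporter"} if n_channels == 2 else {0: "probe"}
    return AcquisitionConfig(
        pixel_size=geometry.pixel_size,
        frame_interval=params.frame_interval,
        channel_roles=roles,
        event_frames={event: event_frame},
    )


def accumulation_curve(times: np.ndarray, t0: float, baseline: float,
                       amplitude_eff: float, k_acc: float) -> np.ndarray:
    """Saturating site intensity: baseline * (1 + A_eff (1 - e^{-k (t-t0)})) for t >= t0."""
    times = np.asarray(times, dtype=float)
    rise = np.where(times >= t0, 1.0 - np.exp(-k_acc * np.maximum(times - t0, 0.0)), 0.0)
    return baseline * (1.0 + amplitude_eff * rise)


def simulate_rupture_timelapse(
    geometry: SceneGeometry, params: SimulationParams
) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel rupture time lapse (probe + NLS reporter).

    The probe accumulates at the 2-um site ROI with effective amplitude
    ``amplitude * pool_fraction`` (zero if the pool was photobleached before
    rupture), reflecting that only the diffusible nucleoplasmic pool feeds
    the rupture site. The reporter leaks by first-order exchange while the
    rupture is open. FRAP cannot be combined with rupture in one stack; the
    regimes are separate experiments.
    """
    geometry.validate()
    params.validate()
    if params.frap is not None:
        raise ConfigurationError(
            "FRAP and rupture are separate regimes; use simulate_frap_timelapse"
        )

    labels = make_scene(geometry)
    nucleus = (labels == LABEL_NE_RIM) | (labels == LABEL_NUCLEOPLASM)
    rim = labels == LABEL_NE_RIM
    nucleoplasm = labels == LABEL_NUCLEOPLASM
    cytoplasm = labels == LABEL_CYTOPLASM
    cell = cytoplasm | nucleus
    site = _site_roi_mask(geometry, params.site_diameter) & cell

    times = np.arange(params.n_frames) * params.frame_interval
    t0 = params.rupture_frame * params.frame_interval
    bg = params.background

    # Probe channel: pool vs assembled-rim partition of the probe signal.
    pool_scale = POOL_BLEACH_RESIDUAL if params.pool_bleached else 1.0
    u_pool = params.probe_level * params.pool_fraction * pool_scale
    u_rim = params.probe_level * (1.0 - params.pool_fraction) * RIM_ENRICHMENT + u_pool
    amplitude_eff = 0.0 if params.pool_bleached else params.amplitude * params.pool_fraction
    site_trace = accumulation_curve(times, t0, u_rim + bg, amplitude_eff, params.k_acc)

    # Reporter channel: two-compartment leak.
    n_t, c_t = reporter_leak_solution(
        times, t0, params.leak_conductance, params.reseal_time,
        params.V_n, params.V_c, params.reporter_level, params.reporter_cyto0,
    )

    ny, nx = geometry.image_shape
    data = np.zeros((params.n_frames, 2, ny, nx), dtype=float)
    for f in range(params.n_frames):
        probe = np.zeros((ny, nx), dtype=float)
        probe[cell] = bg
        probe[nucleoplasm] += u_pool
        probe[rim] += u_rim
        probe[site] = site_trace[f]
        reporter = np.zeros((ny, nx), dtype=float)
        reporter[cell] = bg
        reporter[nucleus] += n_t[f]
        reporter[cytoplasm] += c_t[f]
        data[f, 0] = probe
        data[f, 1] = reporter

    if params.beta > 0:
        data *= np.exp(-params.beta * np.arange(params.n_frames))[:, None, None, None]
    if params.noise is not None:
        data = apply_noise(data, params.noise, params.seed)

    truth = GroundTruth(
        times=times,
        traces={
            "site": site_trace,
            "ne_ring": np.full_like(times, u_rim + bg, dtype=float),
            "nucleoplasm": np.full_like(times, u_pool + bg, dtype=float),
            "reporter_nucleus": n_t + bg,
            "reporter_cytoplasm": c_t + bg,
        },
        masks={
            "nucleus": nucleus,
            "cell": cell,
            "site": site,
            "ne_ring": rim & ~site,
            "nucleoplasm": nucleoplasm & ~site,
            "cytoplasm": cytoplasm & ~site,
        },
        params=params,
        geometry=geometry,
    )
    acq = _acquisition(geometry, params, "irradiation", params.rupture_frame, 2)
    return ImageStack(data=data, acquisition=acq), truth


def default_frap_params(**overrides) -> SimulationParams:
    """FRAP protocol defaults: 5 pre-bleach frames, 60 post at 500 ms."""
    params = SimulationParams(
        frame_interval=0.5,
        n_frames=65,
        rupture_frame=0,
        leak_conductance=0.0,
        amplitude=0.0,
        frap=FrapParams(),
    )
    for key, value in overrides.items():
        setattr(params, key, value)
    return params


def simulate_frap_timelapse(
    geometry: SceneGeometry, params: SimulationParams
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-channel FRAP stack: uniform nucleoplasmic signal,
    a circular bleach spot, exponential recovery with a mobile fraction.

    Spot intensity for ``t >= t_bleach`` is
    ``I_pre * (b + M (1 - b)(1 - e^{-k_rec (t - t_bleach)}))`` with post-bleach
    floor ``b`` and mobile fraction ``M``; the reference region is untouched
    except by acquisition bleaching and noise.
    """
    geometry.validate()
    params.validate()
    if params.frap is None:
        raise ConfigurationError("params.frap must be set for a FRAP simulation")
    frap = params.frap

    labels = make_scene(geometry)
    nucleus = (labels == LABEL_NE_RIM) | (labels == LABEL_NUCLEOPLASM)
    cytoplasm = labels == LABEL_CYTOPLASM
    cell = nucleus | cytoplasm
    cy, cx = geometry.center()
    spot = rasterize_circle(
        CircleROI(center=(cy, cx), diameter=frap.spot_diameter,
                  pixel_size=geometry.pixel_size),
        geometry.image_shape,
    )

    times = np.arange(params.n_frames) * params.frame_interval
    t_bleach = frap.bleach_frame * params.frame_interval
    bg = params.background
    i_pre = params.probe_level
    b, m = frap.bleach_depth, frap.mobile_fraction
    rec = 1.0 - np.exp(-frap.k_rec * np.maximum(times - t_bleach, 0.0))
    spot_sig = np.where(times >= t_bleach, i_pre * (b + m * (1.0 - b) * rec), i_pre)

    ny, nx = geometry.image_shape
    data = np.zeros((params.n_frames, 1, ny, nx), dtype=float)
    for f in range(params.n_frames):
        frame = np.zeros((ny, nx), dtype=float)
        frame[cell] = bg
        frame[nucleus] += i_pre
        frame[spot & nucleus] = spot_sig[f] + bg
        data[f, 0] = frame

    if params.beta > 0:
        data *= np.exp(-params.beta * np.arange(params.n_frames))[:, None, None, None]
    if params.noise is not None:
        data = apply_noise(data, params.noise, params.seed)

    truth = GroundTruth(
        times=times,
        traces={
            "spot": spot_sig + bg,
            "reference": np.full_like(times, i_pre + bg, dtype=float),
            "background": np.zeros_like(times, dtype=float),
        },
        masks={
            "nucleus": nucleus,
            "cell": cell,
            "spot": spot & nucleus,
            "reference": nucleus & ~spot,
            "background": ~cell,
        },
        params=params,
        geometry=geometry,
    )
    acq = _acquisition(geometry, params, "bleach", frap.bleach_frame, 1)
    return ImageStack(data=data, acquisition=acq), truth


def apply_noise(stack: np.ndarray, noise: NoiseParams, seed: int) -> np.ndarray:
    """Apply per-pixel shot noise (Poisson, scaled by the photon gain) then
    additive Gaussian read noise. Deterministic for a fixed seed."""
    noise.validate()
    rng = np.random.default_rng(seed)
    out = np.asarray(stack, dtype=float)
    if noise.photon_gain is not None and np.isfinite(noise.photon_gain):
        out = rng.poisson(np.clip(out, 0.0, None) * noise.photon_gain) / noise.photon_gain
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return out
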