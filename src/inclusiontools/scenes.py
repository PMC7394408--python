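"""Seeded synthetic scenes, FRAP series and cytometry populations.

Every analysis stage in this package is exercised against synthetic inputs
with known ground truth, so no raw microscopy or cytometry data is needed to
test it. This module generates three kinds of input:

* **Scenes** — single cells with one inclusion body, rendered as multi-channel
  2D images. Each channel carries a radial intensity profile relative to the
  inclusion (uniform core, boundary-straddling enriched shell, surface coat of
  given pixel depth, or signal excluded from the inclusion), on top of a flat
  background, with optional additive Gaussian noise (clipped at zero).
* **FRAP series** — a pre-bleach frame followed by post-bleach frames in which
  one half-disk of the inclusion (split by a vertical diameter through the
  inclusion centre) is bleached by a given depth and recovers with
  single-exponential kinetics ``mobile_fraction * (1 - 2**(-t/halftime))``.
* **Cytometry populations** — per-cell event tables with log-normal expression,
  a logistic inclusion probability (optionally modulated by a co-expressed
  modifier protein), pulse-shape shifts for inclusion-bearing events, and
  dual-reporter (GFP/mCherry) stall populations.

Every generator emits a ground-truth record alongside its output; analysis
operations never consume the ground truth. All randomness is controlled by the
seed in the spec; per-channel and per-frame RNG streams are derived from the
seed plus a stable CRC of the channel name so that changing one channel's
profile leaves the other channels' pixels bit-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError
from .image import MultiChannelImage
from .roi import PixelROI

# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------


def uniform(level: float) -> dict:
    """Uniform signal throughout the inclusion disk."""
    return {"kind": "uniform", "level": float(level)}


def shell(inner_level: float, outer_level: float, shell_fraction: float) -> dict:
    """Shell-enriched profile: ``inner_level`` for d/r <= shell_fraction, and
    ``outer_level`` in the rim ``shell_fraction <= d/r <= 2 - shell_fraction``
    straddling the inclusion boundary (surface-enriched co-recruitment)."""
    if not 0 < shell_fraction <= 1:
        raise ValueError("shell_fraction must be in (0, 1]")
    return {"kind": "shell", "inner_level": float(inner_level),
            "outer_level": float(outer_level), "shell_fraction": float(shell_fraction)}


def coat(core_level: float, coat_level: float, coat_depth_px: float) -> dict:
    """Surface coat penetrating ``coat_depth_px`` pixels into the inclusion
    (antibody-staining geometry): coat within the outermost annulus, core
    level inside it, nothing outside the disk."""
    if coat_depth_px < 0:
        raise ValueError("coat_depth_px must be >= 0")
    return {"kind": "coat", "core_level": float(core_level),
            "coat_level": float(coat_level), "coat_depth_px": float(coat_depth_px)}


def excluded(level_outside: float) -> dict:
    """Signal present in the cytoplasm (inside the cell, outside the
    inclusion) and excluded from the inclusion."""
    return {"kind": "excluded", "level_outside": float(level_outside)}


_PROFILE_KINDS = {"uniform", "shell", "coat", "excluded"}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """One cell with one inclusion and named channel profiles.

    Default geometry and intensity levels emulate the imaging conditions of
    the cell system: a single AD293-like cell (radius ~80 px at ~10 px/µm),
    one bright inclusion, a camera offset background and mild read noise.
    """

    image_shape: tuple = (200, 200)
    cell_center: tuple = (100.0, 100.0)
    cell_radius: float = 80.0
    inclusion_center: tuple = (100.0, 100.0)
    inclusion_radius: float = 20.0
    channel_profiles: dict = field(default_factory=dict)
    flash_cerulean_ratio_target: float | None = None
    noise_sigma: float = 0.0
    background_level: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        cr, cc = self.cell_center
        ir, ic = self.inclusion_center
        if self.cell_radius <= 0 or self.inclusion_radius <= 0:
            raise GeometryError("radii must be > 0")
        if not (cr - self.cell_radius >= 0 and cr + self.cell_radius < h
                and cc - self.cell_radius >= 0 and cc + self.cell_radius < w):
            raise GeometryError("cell disk not fully inside image")
        d = np.hypot(ir - cr, ic - cc)
        if d + self.inclusion_radius > self.cell_radius:
            raise GeometryError("inclusion disk not fully inside cell disk")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        for name, prof in self.channel_profiles.items():
            if prof.get("kind") not in _PROFILE_KINDS:
                raise ValueError(f"channel {name!r}: unknown profile {prof!r}")
            for key, val in prof.items():
                if key != "kind" and key != "shell_fraction" and val < 0:
                    raise ValueError(f"channel {name!r}: negative level {key}={val}")


@dataclass
class FrapSpec:
    """Half-disk bleach and single-exponential recovery parameters.

    ``n_postbleach_frames`` counts the recovery frames after the immediate
    post-bleach frame t0, so the default 21 yields frames at t = 0..21 min
    (one frame per minute for 21 minutes, plus the pre-bleach frame).
    """

    mobile_fraction: float = 0.0
    recovery_halftime: float = 5.0  # minutes
    bleach_depth: float = 0.8  # fraction of pre-bleach signal removed at t0
    n_postbleach_frames: int = 21
    frame_interval: float = 1.0  # minutes
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.recovery_halftime <= 0:
            raise ValueError("recovery_halftime must be > 0")
        if self.n_postbleach_frames < 1 or self.frame_interval <= 0:
            raise ValueError("need >= 1 post-bleach frame at positive interval")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PopulationSpec:
    """Cytometry population parameters.

    Defaults reflect a typical transfected-population acquisition: 50,000
    events (the study collected 50,000-100,000), broad log-normal expression,
    inclusion probability rising with expression, and pulse width/height
    shifts of 30% for inclusion-bearing events (narrower, taller pulses).
    """

    n_events: int = 50_000
    construct: str = "97Q"
    expression_logmean: float = 7.0  # natural-log intensity a.u. (cerulean)
    expression_logsd: float = 1.0
    modifier_logmean: float = 6.0  # natural-log intensity a.u. (TMR)
    modifier_logsd: float = 1.0
    logistic_intercept: float = -9.0
    logistic_beta_expression: float = 1.0
    logistic_beta_modifier: float = 0.0
    pulse_width_shift: float = 0.3
    pulse_height_shift: float = 0.3
    pulse_width_base: float = 50.0
    pulse_width_cv: float = 0.1  # lognormal sigma of the width noise
    stall_efficiency: float = 0.0
    ratio_noise_sigma: float = 0.1  # lognormal sigma of the mCherry/GFP noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if not 0 <= self.stall_efficiency <= 1:
            raise ValueError("stall_efficiency must be in [0, 1]")
        if not 0 <= self.pulse_width_shift < 1:
            raise ValueError("pulse_width_shift must be in [0, 1)")
        if self.pulse_height_shift < 0:
            raise ValueError("pulse_height_shift must be >= 0")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Ground truth emitted beside every synthetic output.

    Never consumed by analysis operations — only by tests and acceptance
    checks comparing measured quantities against the generating parameters.
    """

    inclusion_roi: PixelROI | None = None
    cell_roi: PixelROI | None = None
    channel_profiles: dict = field(default_factory=dict)
    penetration_depth_px: float | None = None
    flash_cerulean_ratio: float | None = None
    mobile_fraction: float | None = None
    recovery_halftime: float | None = None
    background_level: float | None = None

    def to_json(self, path: str | Path) -> None:
        data = {
            "channel_profiles": self.channel_profiles,
            "penetration_depth_px": self.penetration_depth_px,
            "flash_cerulean_ratio": self.flash_cerulean_ratio,
            "mobile_fraction": self.mobile_fraction,
            "recovery_halftime": self.recovery_halftime,
            "background_level": self.background_level,
            "inclusion_roi": self.inclusion_roi.to_rle() if self.inclusion_roi else None,
            "cell_roi": self.cell_roi.to_rle() if self.cell_roi else None,
        }
        Path(path).write_text(json.dumps(data))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _channel_rng(seed: int, name: str, frame: int = 0) -> np.random.Generator:
    """Independent, deterministic stream per (seed, channel, frame)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()), int(frame)])


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _profile_field(prof: dict, spec: SceneSpec) -> np.ndarray:
    """Noise-free signal contribution of one channel profile (no background)."""
    h, w = spec.image_shape
    rr, cc = np.ogrid[:h, :w]
    d = np.hypot(rr - spec.inclusion_center[0], cc - spec.inclusion_center[1])
    r = spec.inclusion_radius
    inside = d <= r
    out = np.zeros((h, w), dtype=float)
    kind = prof["kind"]
    if kind == "uniform":
        out[inside] = prof["level"]
    elif kind == "shell":
        frac = prof["shell_fraction"]
        rim = (d >= frac * r) & (d <= (2 - frac) * r)
        out[inside & ~rim] = prof["inner_level"]
        out[rim] = prof["outer_level"]
    elif kind == "coat":
        depth = prof["coat_depth_px"]
        coat_band = inside & (d >= r - depth)
        out[inside & ~coat_band] = prof["core_level"]
        out[coat_band] = prof["coat_level"]
    elif kind == "excluded":
        cell = _disk_mask(spec.image_shape, spec.cell_center, spec.cell_radius)
        out[cell & ~inside] = prof["level_outside"]
    return out


def render_scene(spec: SceneSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render all channels of a scene; deterministic for a fixed seed."""
    spec.validate()
    channels: dict[str, np.ndarray] = {}
    for name, prof in spec.channel_profiles.items():
        img = spec.background_level + _profile_field(prof, spec)
        if spec.noise_sigma > 0:
            img = img + _channel_rng(spec.seed, name).normal(
                0.0, spec.noise_sigma, size=spec.image_shape
            )
        channels[name] = np.clip(img, 0.0, None)
    image = MultiChannelImage(channels)

    inclusion = PixelROI.from_mask(
        _disk_mask(spec.image_shape, spec.inclusion_center, spec.inclusion_radius)
    )
    cell = PixelROI.from_mask(
        _disk_mask(spec.image_shape, spec.cell_center, spec.cell_radius)
    )
    depth = None
    for prof in spec.channel_profiles.values():
        if prof["kind"] == "coat":
            depth = prof["coat_depth_px"]
    ratio = spec.flash_cerulean_ratio_target
    if ratio is None and {"flash", "cerulean"} <= set(spec.channel_profiles):
        fp, cp = spec.channel_profiles["flash"], spec.channel_profiles["cerulean"]
        if fp["kind"] == "uniform" and cp["kind"] == "uniform" and cp["level"] > 0:
            # measured in-ROI means sit on the background pedestal
            ratio = (fp["level"] + spec.background_level) / (
                cp["level"] + spec.background_level)
    truth = GroundTruth(
        inclusion_roi=inclusion,
        cell_roi=cell,
        channel_profiles={k: dict(v) for k, v in spec.channel_profiles.items()},
        penetration_depth_px=depth,
        flash_cerulean_ratio=ratio,
        background_level=spec.background_level,
    )
    return image, truth


def maturity_scene_spec(
    ratio_target: float,
    cerulean_level: float = 200.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
    **overrides,
) -> SceneSpec:
    """Convenience spec for a FlAsH/Cerulean maturity scene.

    The FlAsH level is chosen so that the in-ROI mean FlAsH:Cerulean ratio —
    measured on top of the background pedestal, as the analysis measures it —
    equals ``ratio_target`` exactly in the noiseless limit.
    """
    background = overrides.get("background_level", SceneSpec.background_level)
    flash_level = ratio_target * (cerulean_level + background) - background
    if flash_level < 0:
        raise ValueError(
            f"ratio_target {ratio_target} unreachable over background "
            f"{background}; raise cerulean_level or lower the background"
        )
    return SceneSpec(
        channel_profiles={
            "cerulean": uniform(cerulean_level),
            "flash": uniform(flash_level),
        },
        flash_cerulean_ratio_target=float(ratio_target),
        noise_sigma=noise_sigma,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# FRAP simulation
# ---------------------------------------------------------------------------


@dataclass
class FrapSeries:
    """A simulated FRAP acquisition: frames plus the generating ground truth."""

    frames: list  # list[MultiChannelImage]; frames[0] is pre-bleach
    times: np.ndarray  # minutes; -frame_interval for pre-bleach, then 0..T
    truth: GroundTruth
    bleached_mask: np.ndarray
    spec: FrapSpec


def _recovery_fraction(t: np.ndarray, spec: FrapSpec) -> np.ndarray:
    return spec.mobile_fraction * (1.0 - 2.0 ** (-t / spec.recovery_halftime))


def simulate_frap(
    frap: FrapSpec,
    scene: SceneSpec | None = None,
    fusion_channel: str = "mcherry",
    flash_channel: str = "flash",
) -> FrapSeries:
    """Simulate a half-disk bleach on an inclusion scene.

    The bleached half is the set of inclusion pixels on or right of the
    vertical diameter through the inclusion centre. The fusion channel drops
    by ``bleach_depth`` at t0 and recovers with single-exponential kinetics;
    the FlAsH channel is bleached without recovery (covalently bound dye), so
    thresholding it on the first post-bleach frame yields the unbleached half.
    """
    frap.validate()
    if scene is None:
        scene = SceneSpec(
            channel_profiles={fusion_channel: uniform(200.0),
                              flash_channel: uniform(100.0)},
            noise_sigma=frap.noise_sigma,
            seed=frap.seed,
        )
    scene.validate()
    h, w = scene.image_shape
    rr, cc = np.ogrid[:h, :w]
    d = np.hypot(rr - scene.inclusion_center[0], cc - scene.inclusion_center[1])
    inside = d <= scene.inclusion_radius
    bleached_half = inside & (cc + np.zeros_like(rr) >= scene.inclusion_center[1])

    base = {
        name: spec_field
        for name, spec_field in (
            (name, _profile_field(prof, scene))
            for name, prof in scene.channel_profiles.items()
        )
    }
    n_frames = frap.n_postbleach_frames + 1  # t0 plus recovery frames
    post_times = np.arange(n_frames) * frap.frame_interval
    times = np.concatenate([[-frap.frame_interval], post_times])

    frames = []
    for fi, t in enumerate(times):
        channels = {}
        for name, signal in base.items():
            img = signal.copy()
            if fi > 0:  # post-bleach
                if name == fusion_channel:
                    rec = _recovery_fraction(np.array([t]), frap)[0]
                    factor = 1.0 - frap.bleach_depth * (1.0 - rec)
                    img[bleached_half] *= factor
                elif name == flash_channel:
                    img[bleached_half] *= 1.0 - frap.bleach_depth
            img = img + scene.background_level
            if frap.noise_sigma > 0:
                img = img + _channel_rng(frap.seed, name, fi).normal(
                    0.0, frap.noise_sigma, size=(h, w)
                )
            channels[name] = np.clip(img, 0.0, None)
        frames.append(MultiChannelImage(channels))

    truth = GroundTruth(
        inclusion_roi=PixelROI.from_mask(inside),
        mobile_fraction=frap.mobile_fraction,
        recovery_halftime=frap.recovery_halftime,
        background_level=scene.background_level,
    )
    return FrapSeries(frames=frames, times=times, truth=truth,
                      bleached_mask=bleached_half, spec=frap)


def simulate_frap_trace(
    frap: FrapSpec,
    signal_level: float = 200.0,
    background_level: float = 10.0,
    roi_area: int = 600,
):
    """Simulate per-frame ROI mean intensities directly (no image rendering).

    Equivalent to rendering :func:`simulate_frap` and averaging over the
    bleached/unbleached/background ROIs: ROI means carry the per-pixel noise
    attenuated by sqrt(ROI area). Used for large replicate sweeps.

    Returns a :class:`~inclusiontools.frap.FrapTrace`.
    """
    from .frap import FrapTrace  # local import to avoid a cycle

    frap.validate()
    rng = np.random.default_rng([int(frap.seed), zlib.crc32(b"trace")])
    n_frames = frap.n_postbleach_frames + 1
    post_times = np.arange(n_frames) * frap.frame_interval
    times = np.concatenate([[-frap.frame_interval], post_times])
    rec = _recovery_fraction(post_times, frap)
    factor = 1.0 - frap.bleach_depth * (1.0 - rec)
    bleached = background_level + signal_level * np.concatenate([[1.0], factor])
    unbleached = background_level + signal_level * np.ones_like(times)
    background = background_level * np.ones_like(times)
    if frap.noise_sigma > 0:
        se = frap.noise_sigma / np.sqrt(roi_area)
        bleached = bleached + rng.normal(0, se, size=times.shape)
        unbleached = unbleached + rng.normal(0, se, size=times.shape)
        background = background + rng.normal(0, se, size=times.shape)
    return FrapTrace(times=times, bleached=bleached, unbleached=unbleached,
                     background=background, n_prebleach=1)


# ---------------------------------------------------------------------------
# cytometry population simulation
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "event_id", "construct", "cerulean_area", "cerulean_height", "cerulean_width",
    "tmr_area", "gfp_area", "mcherry_area", "true_inclusion",
]


def simulate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Simulate a cytometry event table with ground-truth inclusion flags.

    Cerulean and TMR pulse areas are log-normal; the inclusion flag is
    Bernoulli with logit ``intercept + beta_e*log(cerulean) + beta_m*log(tmr)``;
    inclusion-bearing events get pulse width multiplied by
    ``1 - pulse_width_shift`` and height by ``1 + pulse_height_shift``.
    Stall populations emit GFP and mCherry areas with
    ``E[mCherry]/E[GFP] = 1 - stall_efficiency``.
    """
    spec.validate()
    rng = np.random.default_rng(int(spec.seed))
    n = spec.n_events
    cerulean = rng.lognormal(spec.expression_logmean, spec.expression_logsd, n)
    tmr = rng.lognormal(spec.modifier_logmean, spec.modifier_logsd, n)

    logit = (spec.logistic_intercept
             + spec.logistic_beta_expression * np.log(cerulean)
             + spec.logistic_beta_modifier * np.log(tmr))
    prob = 1.0 / (1.0 + np.exp(-logit))
    has_inclusion = rng.random(n) < prob

    # pulse area is conserved when fluorescence concentrates into an inclusion:
    # the narrowed pulse is correspondingly taller, and the shape change adds
    # a further height gain on top.
    width = spec.pulse_width_base * rng.lognormal(0.0, spec.pulse_width_cv, n)
    width = np.where(has_inclusion, width * (1.0 - spec.pulse_width_shift), width)
    height = cerulean / width
    height = np.where(has_inclusion, height * (1.0 + spec.pulse_height_shift), height)

    gfp = rng.lognormal(spec.expression_logmean, spec.expression_logsd, n)
    ratio_noise = rng.lognormal(0.0, spec.ratio_noise_sigma, n)
    mcherry = gfp * (1.0 - spec.stall_efficiency) * ratio_noise

    df = pd.DataFrame({
        "event_id": np.arange(n),
        "construct": spec.construct,
        "cerulean_area": cerulean,
        "cerulean_height": height,
        "cerulean_width": width,
        "tmr_area": tmr,
        "gfp_area": gfp,
        "mcherry_area": mcherry,
        "true_inclusion": has_inclusion,
        "true_probability": prob,  # ground truth, never consumed by analyses
    })
    df.attrs["spec"] = asdict(spec)
    return df


def stall_population(
    construct: str,
    stall_efficiency: float,
    n_events: int = 50_000,
    seed: int = 0,
    **overrides,
) -> pd.DataFrame:
    """Dual-reporter (GFP-test-mCherry) population for one construct."""
    spec = PopulationSpec(
        n_events=n_events, construct=construct,
        stall_efficiency=stall_efficiency,
        logistic_intercept=-30.0,  # stall populations carry no inclusions
        seed=seed, **overrides,
    )
    return simulate_population(spec)
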