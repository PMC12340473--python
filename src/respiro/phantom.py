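"""Synthetic breathing-thorax phantom.

Generates paired (cine image series, spirometry airflow) data with the
structure the prediction pipeline assumes: a 2-D short-axis "thorax" per
slice whose diaphragm dome and chest wall move linearly with the
instantaneous lung volume, imaged at ~30 frames/s while airflow is sampled
at 125 Hz on a shared clock starting at t = 0.  Slices are acquired
sequentially, each owning its own contiguous time window, mirroring a
multi-slice cardiac volumetry.

The motion model is deliberately analytic: diaphragm displacement (mm) is a
per-slice gain times the instantaneous volume (L), with the gain largest in
basal slices and smallest apically, plus a radial chest-wall expansion.
This keeps an exact ground truth against which optical-flow and regression
recovery can be scored.

Intensities: background 0, tissue plateaus in [0.3, 1.0], Gaussian pixel
noise added last and the result clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .dataio import FlowTrace, FrameSeries, SliceStack, VolumeTrace, write_series, write_trace
from .errors import CoverageError, ValidationError

__all__ = [
    "Breath",
    "PhantomConfig",
    "PhantomScene",
    "make_breath_pattern",
    "breath_pattern_for_duration",
    "synthesize_airflow",
    "render_scene",
]


@dataclass(frozen=True)
class Breath:
    """One breathing cycle: tidal volume (L), period (s) and pattern type."""

    amplitude_l: float
    period_s: float
    kind: str = "normal"  # "normal" | "deep"

    def __post_init__(self) -> None:
        if not self.amplitude_l > 0:
            raise ValidationError(f"breath amplitude must be positive, got {self.amplitude_l}")
        if not self.period_s > 0:
            raise ValidationError(f"breath period must be positive, got {self.period_s}")
        if self.kind not in ("normal", "deep"):
            raise ValidationError(f"unknown breath kind {self.kind!r}")


@dataclass
class PhantomConfig:
    """Stated world for one synthetic subject.

    Defaults mirror the imaging geometry the pipeline was designed for:
    200x200 pixel frames at 33 ms per frame, 19 slices of 900 frames each,
    spirometry at 125 Hz.  ``diaphragm_gain_mm_per_l`` is the basal-slice
    diaphragm excursion per litre of lung volume (~30 mm/L puts tidal
    excursion at a physiological ~15 mm for a 0.5 L breath); it is a free
    phantom parameter, not a fitted physiological constant.
    """

    breath_pattern: tuple[Breath, ...]
    image_size: int = 200
    frame_period: float = 0.033
    flow_rate_hz: float = 125.0
    n_slices: int = 19
    frames_per_slice: int = 900
    noise_sd: float = 0.02
    rotation_deg: float = 0.0
    seed: int = 0
    noise_seed: int | None = None  # defaults to `seed`; set for a re-scan of the same anatomy
    pixel_size_mm: float = 1.8
    diaphragm_gain_mm_per_l: float = 30.0
    chest_gain_mm_per_l: float = 8.0
    anatomy_jitter: float = 0.05

    def __post_init__(self) -> None:
        self.breath_pattern = tuple(self.breath_pattern)
        if not self.breath_pattern:
            raise ValidationError("breath_pattern must contain at least one breath")
        if self.image_size <= 0:
            raise ValidationError("image_size must be positive")
        if not self.frame_period > 0:
            raise ValidationError("frame_period must be positive")
        if self.flow_rate_hz < 1.0 / self.frame_period:
            raise ValidationError(
                "spirometry rate must be at least the frame rate "
                f"({self.flow_rate_hz} Hz < {1.0 / self.frame_period:.2f} Hz)"
            )
        if self.n_slices < 1 or self.frames_per_slice < 1:
            raise ValidationError("n_slices and frames_per_slice must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def imaging_duration(self) -> float:
        return self.n_slices * self.frames_per_slice * self.frame_period

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = {
            "breath_pattern": [
                {"amplitude_l": b.amplitude_l, "period_s": b.period_s, "kind": b.kind}
                for b in self.breath_pattern
            ],
            "image_size": self.image_size,
            "frame_period": self.frame_period,
            "flow_rate_hz": self.flow_rate_hz,
            "n_slices": self.n_slices,
            "frames_per_slice": self.frames_per_slice,
            "noise_sd": self.noise_sd,
            "rotation_deg": self.rotation_deg,
            "seed": self.seed,
            "noise_seed": self.noise_seed,
            "pixel_size_mm": self.pixel_size_mm,
            "diaphragm_gain_mm_per_l": self.diaphragm_gain_mm_per_l,
            "chest_gain_mm_per_l": self.chest_gain_mm_per_l,
            "anatomy_jitter": self.anatomy_jitter,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        breaths = tuple(Breath(**b) for b in d.pop("breath_pattern"))
        return cls(breath_pattern=breaths, **d)


def make_breath_pattern(
    n_normal: int,
    n_deep: int = 0,
    tidal_volume_l: float = 0.5,
    period_s: float = 3.0,
    deep_volume_scale: float = 2.5,
    deep_period_scale: float = 1.4,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Breath, ...]:
    """Deep breaths followed by normal breaths, optionally jittered.

    Jitter is uniform and bounded (+-``jitter`` fraction on both amplitude and
    period) so worst-case breath durations stay predictable.
    """
    if n_normal + n_deep < 1:
        raise ValidationError("at least one breath is required")
    if jitter and rng is None:
        rng = np.random.default_rng(0)

    def _jit() -> float:
        return 1.0 + jitter * rng.uniform(-1.0, 1.0) if jitter else 1.0

    breaths = []
    for _ in range(n_deep):
        breaths.append(
            Breath(
                amplitude_l=tidal_volume_l * deep_volume_scale * _jit(),
                period_s=period_s * deep_period_scale * _jit(),
                kind="deep",
            )
        )
    for _ in range(n_normal):
        breaths.append(
            Breath(amplitude_l=tidal_volume_l * _jit(), period_s=period_s * _jit(), kind="normal")
        )
    return tuple(breaths)


def breath_pattern_for_duration(
    duration_s: float,
    tidal_volume_l: float = 0.5,
    period_s: float = 3.0,
    jitter: float = 0.05,
    rng: np.random.Generator | None = None,
    margin_s: float = 2.0,
) -> tuple[Breath, ...]:
    """Append jittered tidal breaths until they cover ``duration_s`` (+ margin)."""
    if rng is None:
        rng = np.random.default_rng(0)
    breaths: list[Breath] = []
    total = 0.0
    while total < duration_s + margin_s:
        amp = tidal_volume_l * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        per = period_s * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        breaths.append(Breath(amplitude_l=amp, period_s=per))
        total += per
    return tuple(breaths)


def synthesize_airflow(config: PhantomConfig) -> FlowTrace:
    """Continuous airflow waveform built from per-breath sinusoidal lobes.

    Each breath of tidal volume A and period T contributes
    ``f(t) = (pi * A / T) * sin(2 pi t / T)``: the inspiratory half-cycle
    integrates to exactly A litres and the full cycle to zero, so tidal
    cycles are closed.
    """
    rate = config.flow_rate_hz
    periods = np.array([b.period_s for b in config.breath_pattern])
    amps = np.array([b.amplitude_l for b in config.breath_pattern])
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    duration = starts[-1]
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    which = np.searchsorted(starts[1:], t, side="right")
    which = np.clip(which, 0, len(periods) - 1)
    phase = (t - starts[which]) / periods[which]
    flow_amp = np.pi * amps[which] / periods[which]
    return FlowTrace(values=flow_amp * np.sin(2.0 * np.pi * phase), rate=rate, t0=0.0)


def integrate_flow_physical(flow: FlowTrace) -> VolumeTrace:
    """Ground-truth lung volume in mL: 1000 * cumulative left-Riemann integral."""
    values = 1000.0 * np.cumsum(flow.values) / flow.rate
    return VolumeTrace(values=values, rate=flow.rate, t0=flow.t0)


@dataclass
class _SliceGeometry:
    """Per-slice anatomy in pixel units."""

    a0: float  # torso semi-axis, x
    b0: float  # torso semi-axis, y
    dome_y0: float  # diaphragm dome apex offset from centre (px, +down)
    dome_curv: float
    dome_width: float
    dia_gain_px_per_l: float
    chest_gain_px_per_l: float
    heart_x: float
    heart_y: float
    heart_sigma: float


@dataclass
class PhantomScene:
    """A rendered (lazily, per slice) phantom subject.

    Holds the analytic ground truth — airflow, physically integrated volume
    and per-slice diaphragm displacement — while image frames are rendered
    on demand by :meth:`series` so a full-size scene never has to keep all
    slices in memory at once.
    """

    config: PhantomConfig
    flow: FlowTrace
    volume: VolumeTrace  # mL, at the spirometry rate
    displacement_mm: np.ndarray  # (n_slices, len(flow)) diaphragm displacement
    _geometry: list[_SliceGeometry] = field(repr=False, default_factory=list)

    def series(self, slice_index: int) -> FrameSeries:
        """Render one slice's frame series (deterministic under the config seed)."""
        cfg = self.config
        if not 0 <= slice_index < cfg.n_slices:
            raise ValidationError(f"slice_index {slice_index} out of range")
        geom = self._geometry[slice_index]
        n_frames = cfg.frames_per_slice
        t0 = slice_index * n_frames * cfg.frame_period
        frame_times = t0 + np.arange(n_frames) * cfg.frame_period
        vol_l = np.interp(frame_times, self.flow.times, self.volume.values / 1000.0)

        size = cfg.image_size
        c = (size - 1) / 2.0
        yy, xx = np.meshgrid(np.arange(size) - c, np.arange(size) - c, indexing="ij")
        th = np.deg2rad(cfg.rotation_deg)
        xr = np.cos(th) * xx + np.sin(th) * yy
        yr = -np.sin(th) * xx + np.cos(th) * yy

        noise_entropy = cfg.seed if cfg.noise_seed is None else cfg.noise_seed
        rng = np.random.default_rng(
            np.random.SeedSequence(noise_entropy).spawn(cfg.n_slices + 1)[slice_index + 1]
        )
        edge = max(2.0, 0.02 * size)  # spatial softness of tissue boundaries (px)
        heart = 0.25 * np.exp(
            -((xr - geom.heart_x) ** 2 + (yr - geom.heart_y) ** 2) / (2.0 * geom.heart_sigma**2)
        )

        frames = np.empty((n_frames, size, size), dtype=np.float32)
        for l in range(n_frames):
            v = vol_l[l]
            a = geom.a0 + geom.chest_gain_px_per_l * v
            b = geom.b0 + geom.chest_gain_px_per_l * v
            rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
            w_rho = edge / b
            inside = _sigmoid((1.0 - rho) / w_rho)
            wall = inside * _sigmoid((rho - 0.86) / w_rho)
            y_dome = geom.dome_y0 + geom.dome_curv * (xr / geom.a0) ** 2 - geom.dia_gain_px_per_l * v
            dome = _sigmoid((yr - y_dome) / geom.dome_width)
            interior = np.minimum(0.32 + heart + 0.55 * dome, 0.95)
            img = inside * interior
            img = img * (1.0 - wall) + 0.88 * wall
            if cfg.noise_sd > 0:
                img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
            np.clip(img, 0.0, 1.0, out=img)
            frames[l] = img.astype(np.float32)
        return FrameSeries(
            frames=frames,
            frame_period=cfg.frame_period,
            slice_index=slice_index,
            orientation_deg=cfg.rotation_deg,
            t0=t0,
        )

    def stack(self, gap_mm: float = 8.0) -> SliceStack:
        """Render every slice eagerly (small scenes only)."""
        return SliceStack(series=[self.series(s) for s in range(self.config.n_slices)], gap_mm=gap_mm)

    def save(self, out_dir: str | Path) -> Path:
        """Write per-slice NIfTIs, flow/volume CSVs and the config YAML."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in range(self.config.n_slices):
            write_series(self.series(s), out_dir / f"slice_{s:02d}.nii")
        write_trace(self.flow, out_dir / "flow.csv")
        write_trace(self.volume, out_dir / "volume.csv")
        self.config.to_yaml(out_dir / "phantom.yaml")
        return out_dir


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def render_scene(config: PhantomConfig, flow: FlowTrace | None = None) -> PhantomScene:
    """Build a phantom scene driven by ``flow`` (default: the config's pattern).

    The flow trace must cover the full imaging duration
    (``n_slices * frames_per_slice * frame_period`` seconds).
    """
    if flow is None:
        flow = synthesize_airflow(config)
    needed = config.imaging_duration
    if flow.t0 > 1e-9 or flow.duration < needed - 1e-9:
        raise CoverageError(
            f"flow trace covers {flow.duration:.2f} s from t0={flow.t0:.2f} s but the "
            f"scene requires [0, {needed:.2f}) s"
        )
    volume = integrate_flow_physical(flow)

    anat_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(config.n_slices + 1)[0])
    j = config.anatomy_jitter

    def _jit() -> float:
        return 1.0 + j * anat_rng.uniform(-1.0, 1.0) if j else 1.0

    size = config.image_size
    subj_scale = _jit()
    subj_gain = _jit()
    subj_dome = _jit()
    geometry: list[_SliceGeometry] = []
    n = config.n_slices
    for s in range(n):
        sfrac = s / (n - 1) if n > 1 else 0.0
        # basal slices (index 0) carry the largest diaphragm excursion
        dia_gain_mm = config.diaphragm_gain_mm_per_l * (1.0 - 0.65 * sfrac) * subj_gain
        chest_gain_mm = config.chest_gain_mm_per_l * (0.7 + 0.5 * sfrac) * subj_gain
        geometry.append(
            _SliceGeometry(
                a0=0.42 * size * subj_scale,
                b0=0.38 * size * subj_scale,
                dome_y0=(0.10 + 0.10 * sfrac) * size * subj_dome,
                dome_curv=0.08 * size,
                dome_width=max(2.0, 0.02 * size),
                dia_gain_px_per_l=dia_gain_mm / config.pixel_size_mm,
                chest_gain_px_per_l=chest_gain_mm / config.pixel_size_mm,
                heart_x=-0.06 * size,
                heart_y=-0.08 * size,
                heart_sigma=0.07 * size,
            )
        )

    vol_l = volume.values / 1000.0
    disp = np.empty((n, len(flow)))
    for s in range(n):
        disp[s] = config.diaphragm_gain_mm_per_l * (1.0 - 0.65 * (s / (n - 1) if n > 1 else 0.0)) * subj_gain * vol_l

    return PhantomScene(
        config=config, flow=flow, volume=volume, displacement_mm=disp, _geometry=geometry
    )
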