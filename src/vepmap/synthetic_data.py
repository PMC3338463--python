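"""Ground-truth generators for every pipeline stage.

Every generator is a pure function of (specification, seed): identical
inputs give bit-identical outputs.  The VEP generator drives a small set of
equivalent dipoles at published group-average coordinates of
motion-responsive visual areas with Gaussian-windowed component waveforms
peaking at the motion-VEP component latencies; the earliest (striate)
component and the motion-offset response invert polarity between upper- and
lower-field stimulation.  BOLD generators cover the 16 s ON/OFF block
design and the 64 s/cycle phase-encoded design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coregister import GROUP_FMRI_CENTROIDS, stereotaxic_to_head
from .fmri_stats import DesignSpec, VolumeSeries, canonical_hrf
from .forward_model import ElectrodeMontage, HeadModel, leadfield
from .vep_pipeline import RawRecording

__all__ = [
    "ComponentSpec",
    "ScenarioSpec",
    "GroundTruth",
    "make_component_templates",
    "default_dipoles",
    "simulate_vep_session",
    "inject_artifacts",
    "simulate_block_fmri",
    "simulate_retinotopy_phantom",
]

QUADRANTS = ("UL", "UR", "LL", "LR")

# Fixed dipole orientations (unit vectors, head frame) per source label,
# chosen once so the six sources project distinct scalp topographies
# (pairwise pattern correlation <= ~0.42) — the spatial distinctness that
# makes the named VEP components separable in real recordings.  Signs follow
# the convention that each source's peak posterior channel is positive for a
# positive moment, so polarity-inverting components are scalp-negative for
# upper-field stimulation.
_DIPOLE_ORIENTATIONS = {
    "Calcarine": (-0.556, -0.752, 0.354),
    "MT+": (0.657, -0.475, -0.585),
    "pIPS": (-0.061, -0.528, 0.847),
    "LOR": (-0.983, 0.182, 0.007),
    "IPS": (0.051, -0.448, -0.892),
    "POS": (0.244, -0.039, 0.969),
}

# extra dorsal parieto-occipital source present in fast-motion scenarios
_POS_COORD_UPPER = (18.0, -82.0, 42.0)
_POS_COORD_LOWER = (12.0, -80.0, 37.0)


@dataclass(frozen=True)
class ComponentSpec:
    """One VEP component: a Gaussian-windowed deflection of one dipole."""

    name: str
    latency_ms: float
    width_ms: float
    amplitude_nam: float
    polarity_rule: str  # "invert" (upper/lower field) or "fixed"
    dipole: str
    rise_fraction: float = 0.45  # rise sd as a fraction of the nominal sd

    def __post_init__(self) -> None:
        if not 0 <= self.latency_ms <= 1000:
            raise ValueError("latency must lie in 0-1000 ms")
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if self.polarity_rule not in ("invert", "fixed"):
            raise ValueError("polarity_rule must be 'invert' or 'fixed'")


def make_component_templates(speed: str) -> list[ComponentSpec]:
    """Component set for one motion speed.

    Slow motion: C1 at 100 ms (striate, polarity-inverting), P120 at 120 ms
    (MT+), N160 at 160 ms (pIPS), N180 at 180 ms (LOR), P250 at 250 ms
    (IPS) and the offset response oC1 at 350 ms reusing the striate source.
    Fast motion adds N70 at 70 ms (MT+) and shifts the posterior N2 peak to
    170 ms.
    """
    common = [
        ComponentSpec("C1", 100, 40, 28.0, "invert", "Calcarine"),
        ComponentSpec("P120", 120, 45, 22.0, "fixed", "MT+"),
        ComponentSpec("N180", 180, 45, 18.0, "fixed", "LOR"),
        ComponentSpec("P250", 250, 80, 30.0, "fixed", "IPS"),
        ComponentSpec("oC1", 350, 40, 16.0, "invert", "Calcarine"),
    ]
    if speed == "slow":
        n2 = [ComponentSpec("N160", 160, 45, 20.0, "fixed", "pIPS")]
        extra = []
    elif speed == "fast":
        n2 = [ComponentSpec("N170", 170, 45, 24.0, "fixed", "pIPS")]
        extra = [ComponentSpec("N70", 70, 30, 12.0, "fixed", "MT+")]
    else:
        raise ValueError(f"unknown speed {speed!r}")
    comps = extra + common[:2] + n2 + common[2:]
    return sorted(comps, key=lambda c: c.latency_ms)


def default_dipoles(speed: str, quadrant: str = "UR") -> dict[str, np.ndarray]:
    """Ground-truth dipole positions (head frame mm) for one scenario.

    Positions are the group-average fMRI activation centroids of the five
    motion-VEP sources, mapped into the spherical head frame; fast scenarios
    add the dorsal parieto-occipital (POS/V6) source.
    """
    key = "slow/upper" if speed == "slow" else "fast/upper"
    rois = GROUP_FMRI_CENTROIDS[key]
    labels = ["Calcarine", "MT+", "pIPS", "LOR", "IPS"]
    out = {lab: stereotaxic_to_head(np.array(rois[lab])) for lab in labels}
    if speed == "fast":
        pos = _POS_COORD_UPPER if quadrant in ("UL", "UR") else _POS_COORD_LOWER
        out["POS"] = stereotaxic_to_head(np.array(pos))
    return out


@dataclass
class ScenarioSpec:
    """A complete synthetic VEP session specification."""

    speed: str = "slow"
    quadrant: str = "UR"
    seed: int = 0
    n_trials: int = 525
    soa_ms: tuple[float, float] = (650.0, 1000.0)
    snr: float = 10.0  # RMS signal / RMS noise at the peak channel; inf = noiseless
    artifact_rate: float = 0.0
    sfreq: float = 250.0
    dipoles: dict[str, np.ndarray] = None
    components: list[ComponentSpec] = None
    pink_fraction: float = 0.5  # fraction of noise power that is 1/f

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"quadrant must be one of {QUADRANTS}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not self.snr > 0:
            raise ValueError("SNR must be positive")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.dipoles is None:
            self.dipoles = default_dipoles(self.speed, self.quadrant)
        if self.components is None:
            self.components = make_component_templates(self.speed)
        missing = {c.dipole for c in self.components} - set(self.dipoles)
        if missing:
            raise ValueError(f"components reference unknown dipoles {missing}")

    @property
    def condition(self) -> str:
        return f"{self.speed}/{self.quadrant}"

    @property
    def upper_field(self) -> bool:
        return self.quadrant in ("UL", "UR")


@dataclass
class GroundTruth:
    """Truth bundle returned alongside every generated dataset."""

    dipole_positions: dict = field(default_factory=dict)
    dipole_orientations: dict = field(default_factory=dict)
    moment_templates: dict = field(default_factory=dict)  # label -> (times_ms, nA·m)
    component_latencies: dict = field(default_factory=dict)
    event_samples: np.ndarray | None = None
    artifact_flags: np.ndarray | None = None
    roi_centroids: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _component_sign(comp: ComponentSpec, upper_field: bool) -> float:
    """Moment sign; polarity-inverting components flip with hemifield.

    The convention places the striate (C1-generating) moment negative for
    upper-field and positive for lower-field stimulation, matching the
    scalp-negative upper-field C1 at occipito-parietal sites.
    """
    if comp.polarity_rule == "invert":
        return -1.0 if upper_field else 1.0
    return 1.0


def _moment_templates(
    scenario: ScenarioSpec, times_ms: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-dipole moment time course (nA·m) over one epoch."""
    out = {lab: np.zeros_like(times_ms) for lab in scenario.dipoles}
    for comp in scenario.components:
        # asymmetric deflection: steep rise, slower decay.  The nominal FWHM
        # splits into a rise sd (rise_fraction x sigma) and a fall sd
        # ((2 - rise_fraction) x sigma), emulating the brisk onset of
        # motion-onset components while keeping windowed fits well posed.
        sigma = comp.width_ms / 2.355  # FWHM -> sd
        s_rise = comp.rise_fraction * sigma
        s_fall = (2.0 - comp.rise_fraction) * sigma
        dt = times_ms - comp.latency_ms
        shape = np.where(
            dt < 0,
            np.exp(-0.5 * (dt / s_rise) ** 2),
            np.exp(-0.5 * (dt / s_fall) ** 2),
        )
        bump = comp.amplitude_nam * shape
        out[comp.dipole] = out[comp.dipole] + _component_sign(
            comp, scenario.upper_field
        ) * bump
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f-spectrum noise, channels × samples."""
    n_ch, n_s = shape
    white = rng.standard_normal((n_ch, n_s))
    X = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_s)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(X * scale, n=n_s, axis=1)
    return pink / pink.std(axis=1, keepdims=True)


def simulate_vep_session(
    scenario: ScenarioSpec,
    head: HeadModel | None = None,
    montage: ElectrodeMontage | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Continuous synthetic VEP recording with events and ground truth.

    Per-trial component waveforms are forward-projected through the
    three-shell head model and summed into a continuous recording, with a
    1/f + white noise mixture scaled so that RMS signal / RMS noise at the
    peak channel equals ``scenario.snr``.  Artifacts are injected afterwards
    if ``artifact_rate`` > 0.
    """
    from .forward_model import make_standard_montage

    head = head or HeadModel()
    montage = montage or make_standard_montage(outer_radius=head.outer_radius)
    rng = np.random.default_rng(scenario.seed)
    sf = scenario.sfreq

    # epoch template: -100..+1000 ms
    n_epoch = int(round(1.1 * sf))
    times_ms = -100.0 + np.arange(n_epoch) * 1000.0 / sf
    moments = _moment_templates(scenario, times_ms)
    gains = {
        lab: leadfield(head, montage, pos).gains
        @ np.asarray(_DIPOLE_ORIENTATIONS.get(lab, (0.0, -0.6, 0.8)), dtype=float)
        / np.linalg.norm(_DIPOLE_ORIENTATIONS.get(lab, (0.0, -0.6, 0.8)))
        for lab, pos in scenario.dipoles.items()
    }
    template = np.zeros((montage.n_channels, n_epoch))
    for lab in scenario.dipoles:
        template += np.outer(gains[lab], moments[lab])

    # event grid with jittered SOA
    soa = rng.uniform(*scenario.soa_ms, size=scenario.n_trials)
    pre_pad = int(round(1.0 * sf))
    onsets = pre_pad + np.cumsum(np.round(soa * sf / 1000.0)).astype(int)
    onsets = onsets - onsets[0] + pre_pad
    n_samples = onsets[-1] + n_epoch + int(round(1.0 * sf))

    data = np.zeros((montage.n_channels, n_samples))
    t0 = int(round(0.1 * sf))  # template starts 100 ms before onset
    for s in onsets:
        data[:, s - t0 : s - t0 + n_epoch] += template

    if np.isfinite(scenario.snr):
        peak_ch = int(np.argmax(np.sqrt(np.mean(template**2, axis=1))))
        sig_rms = np.sqrt(np.mean(template[peak_ch] ** 2))
        pf = scenario.pink_fraction
        noise = math.sqrt(pf) * _pink_noise(rng, data.shape) + math.sqrt(
            1 - pf
        ) * rng.standard_normal(data.shape)
        noise_rms = noise[peak_ch].std()
        data += noise * (sig_rms / (scenario.snr * noise_rms))

    events = [(int(s), scenario.condition) for s in onsets]
    raw = RawRecording(
        data=data, sfreq=sf, labels=list(montage.labels), events=events,
        montage=montage,
    )

    roi_key = "slow/upper" if scenario.speed == "slow" else "fast/upper"
    roi_truth = {
        lab: stereotaxic_to_head(np.array(xyz))
        for lab, xyz in GROUP_FMRI_CENTROIDS[roi_key].items()
    }
    truth = GroundTruth(
        dipole_positions={k: np.asarray(v, float) for k, v in scenario.dipoles.items()},
        dipole_orientations={
            lab: np.asarray(_DIPOLE_ORIENTATIONS.get(lab, (0.0, -0.6, 0.8)), float)
            / np.linalg.norm(_DIPOLE_ORIENTATIONS.get(lab, (0.0, -0.6, 0.8)))
            for lab in scenario.dipoles
        },
        moment_templates={lab: (times_ms.copy(), m) for lab, m in moments.items()},
        component_latencies={c.name: c.latency_ms for c in scenario.components},
        event_samples=onsets.copy(),
        artifact_flags=np.zeros(scenario.n_trials, dtype=bool),
        roi_centroids=roi_truth,
        extras={"scenario": scenario, "scalp_template": template},
    )

    if scenario.artifact_rate > 0:
        raw, flags = inject_artifacts(
            raw, scenario.artifact_rate, seed=scenario.seed + 1
        )
        truth.artifact_flags = flags
    return raw, truth


def inject_artifacts(
    raw: RawRecording,
    rate: float,
    kinds: tuple[str, ...] = ("blink", "excursion"),
    seed: int = 0,
) -> tuple[RawRecording, np.ndarray]:
    """Insert blink-like and high-amplitude artifacts into random trials.

    Blinks are low-frequency frontal-dominant transients (largest at the
    frontopolar sites); excursions are large spikes on one random channel.
    Because successive epochs overlap (stimulus onset asynchrony is shorter
    than the epoch), each artifact is confined to the time range belonging
    exclusively to its own trial's epoch, so truth flags map one-to-one onto
    epochs.  Returns the contaminated recording and per-trial truth flags.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    data = raw.data.copy()
    rng = np.random.default_rng(seed)
    n_trials = len(raw.events)
    flags = rng.random(n_trials) < rate
    sf = raw.sfreq
    n_post = int(round(1.0 * sf))  # epoch extends to +1000 ms
    t0 = int(round(0.1 * sf))  # and starts 100 ms before onset

    # frontal weighting for blink topography
    if raw.montage is not None:
        pos = raw.montage.positions
        w = np.maximum(pos[:, 1], 0.0) * np.maximum(pos[:, 2] + 40.0, 0.0)
        w = w / w.max() if w.max() > 0 else np.ones(len(pos))
    else:
        w = np.ones(data.shape[0])

    onsets = [s for s, _ in raw.events]
    for i, sample in enumerate(onsets):
        if not flags[i]:
            continue
        # exclusive range: after the previous epoch ends, before the next begins
        lo = sample - t0
        if i > 0:
            lo = max(lo, onsets[i - 1] + n_post + 1)
        hi = sample + n_post
        if i + 1 < n_trials:
            hi = min(hi, onsets[i + 1] - t0 - 1)
        lo = max(lo, 0)
        hi = min(hi, data.shape[1])
        if hi - lo < int(0.08 * sf):
            flags[i] = False
            continue
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "blink":
            dur = min(int(round(0.15 * sf)), hi - lo)
            off = lo + int(rng.integers(0, hi - lo - dur + 1))
            amp = rng.uniform(160.0, 250.0)
            shape = amp * np.sin(np.linspace(0, np.pi, dur)) ** 2
            data[:, off : off + dur] += np.outer(w, shape)
        else:
            dur = min(10, hi - lo)
            ch = int(rng.integers(data.shape[0]))
            off = lo + int(rng.integers(0, hi - lo - dur + 1))
            data[ch, off : off + dur] += rng.uniform(250.0, 400.0)
    out = RawRecording(
        data=data, sfreq=raw.sfreq, labels=list(raw.labels),
        events=list(raw.events), montage=raw.montage,
    )
    return out, flags


# --------------------------------------------------------------------------
# BOLD generators
# --------------------------------------------------------------------------


def simulate_block_fmri(
    roi_truth: list[tuple],
    design: DesignSpec | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    voxel_size_mm: float = 3.0,
    margin_mm: float = 12.0,
    ar_rho: float = 0.3,
) -> tuple[VolumeSeries, GroundTruth]:
    """Block-design BOLD series with spherical activation blobs.

    ``roi_truth`` rows are ``(center_mm, radius_mm, amplitude)``; each blob's
    voxels follow boxcar⊗HRF at the stated amplitude plus AR(1) (rho 0.3)
    + white noise.  The affine is chosen so blob centers land at the
    requested mm coordinates.  Overlapping blobs with conflicting amplitudes
    raise.
    """
    design = design or DesignSpec(kind="block")
    centers = np.array([np.asarray(c, float) for c, _, _ in roi_truth])
    radii = np.array([r for _, r, _ in roi_truth])
    amps = np.array([a for _, _, a in roi_truth])

    lo = (centers - radii[:, None]).min(axis=0) - margin_mm
    hi = (centers + radii[:, None]).max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / voxel_size_mm).astype(int) + 1
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = lo

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox_mm = np.stack([ii, jj, kk], axis=-1) * voxel_size_mm + lo

    n_t = design.n_volumes
    task = np.convolve(design.boxcar(), canonical_hrf(design.tr))[:n_t]

    amp_map = np.zeros(tuple(shape))
    claimed = np.zeros(tuple(shape), dtype=bool)
    for c, r, a in zip(centers, radii, amps):
        inside = np.linalg.norm(vox_mm - c, axis=-1) <= r
        conflict = inside & claimed & ~np.isclose(amp_map, a)
        if conflict.any():
            raise ValueError("overlapping blobs with conflicting amplitudes")
        amp_map[inside] = a
        claimed |= inside

    rng = np.random.default_rng(seed)
    data = amp_map[..., None] * task[None, None, None, :]
    if noise_sd > 0:
        white = rng.standard_normal(tuple(shape) + (n_t,))
        ar = np.empty_like(white)
        ar[..., 0] = white[..., 0]
        for t in range(1, n_t):
            ar[..., t] = ar_rho * ar[..., t - 1] + white[..., t]
        ar = ar * math.sqrt(1 - ar_rho**2)  # unit marginal variance
        mix = 0.5 * ar + 0.5 * rng.standard_normal(tuple(shape) + (n_t,))
        data = data + noise_sd * mix / math.sqrt(0.5)
    series = VolumeSeries(
        data=data, tr=design.tr, affine=affine, voxel_size_mm=voxel_size_mm
    )
    truth = GroundTruth(
        roi_centroids={i: c for i, c in enumerate(centers)},
        extras={
            "amplitudes": amps,
            "radii": radii,
            "amp_map": amp_map,
            "task_regressor": task,
        },
    )
    return series, truth


def simulate_retinotopy_phantom(
    lattice: tuple[int, int] = (40, 40),
    n_strips: int = 4,
    design: DesignSpec | None = None,
    snr: float = 3.0,
    hemodynamic_delay_s: float = 5.0,
    amplitude: float = 1.0,
    seed: int = 0,
    polar_sweep: tuple[float, float] = (0.0, 90.0),
    ecc_sweep: tuple[float, float] = (0.0, 8.0),
) -> tuple[dict, GroundTruth]:
    """2D cortical-lattice phantom for phase-encoded retinotopy.

    The lattice is divided into ``n_strips`` horizontal strips emulating
    adjacent visual areas: polar angle sweeps up the strip in mirror strips
    and down in non-mirror strips (alternating), while eccentricity
    increases along x everywhere.  Returns ``{"polar": VolumeSeries,
    "eccentricity": VolumeSeries}`` plus truth with per-voxel coordinates
    and field sign.  ``snr`` is response RMS over noise RMS; ``inf``
    disables noise.
    """
    design = design or DesignSpec(kind="periodic")
    nx, ny = lattice
    n_t = design.n_volumes
    k = design.stimulus_bin

    strip_of = np.minimum((np.arange(ny) * n_strips) // ny, n_strips - 1)
    mirror = np.where(strip_of % 2 == 0, 1, -1)  # +1 mirror strip

    y_frac = np.empty(ny)
    for s in range(n_strips):
        idx = np.flatnonzero(strip_of == s)
        local = np.linspace(0.05, 0.95, len(idx))
        y_frac[idx] = local if s % 2 == 0 else local[::-1]
    x_frac = np.linspace(0.05, 0.95, nx)

    polar_true = polar_sweep[0] + y_frac[None, :] * (polar_sweep[1] - polar_sweep[0])
    polar_true = np.broadcast_to(polar_true, (nx, ny)).copy()
    ecc_true = ecc_sweep[0] + x_frac[:, None] * (ecc_sweep[1] - ecc_sweep[0])
    ecc_true = np.broadcast_to(ecc_true, (nx, ny)).copy()
    sign_true = np.broadcast_to(-mirror[None, :], (nx, ny)).copy()
    # polar angle increases along +y in mirror strips and along -y otherwise,
    # eccentricity always along +x: cross(z) = dp/dx*de/dy - dp/dy*de/dx
    #                                        = -dp/dy * de/dx
    # so mirror strips (dp/dy>0) have sign -1 under the +x/+y convention;
    # truth recorded accordingly.

    rng = np.random.default_rng(seed)
    t_idx = np.arange(n_t)
    delay_frac = hemodynamic_delay_s / design.cycle_s

    def _series(frac_map: np.ndarray, sub: int) -> VolumeSeries:
        theta = 2 * np.pi * (frac_map[..., None] + delay_frac)
        sig = amplitude * np.cos(2 * np.pi * k * t_idx / n_t - theta)
        if np.isfinite(snr):
            sd = amplitude / (np.sqrt(2.0) * snr)
            sig = sig + sd * np.random.default_rng(seed + sub).standard_normal(sig.shape)
        return VolumeSeries(
            data=sig[:, :, None, :], tr=design.tr, voxel_size_mm=1.0
        )

    frac_polar = (polar_true - polar_sweep[0]) / (polar_sweep[1] - polar_sweep[0])
    frac_ecc = (ecc_true - ecc_sweep[0]) / (ecc_sweep[1] - ecc_sweep[0])
    series = {
        "polar": _series(frac_polar, 1),
        "eccentricity": _series(frac_ecc, 2),
    }
    truth = GroundTruth(
        extras={
            "polar_deg": polar_true,
            "eccentricity_deg": ecc_true,
            "field_sign": sign_true,
            "strip_of_column": strip_of,
            "design": design,
            "hemodynamic_delay_s": hemodynamic_delay_s,
            "polar_sweep": polar_sweep,
            "ecc_sweep": ecc_sweep,
        }
    )
    return series, truth
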