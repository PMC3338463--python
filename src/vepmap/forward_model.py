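"""Spherical-head EEG forward model.

Electrode montage handling, best-fit sphere estimation, and the analytic
concentric three-shell forward solution mapping a current dipole (position in
mm, moment in nA·m) to scalp potentials in µV.

The head is modelled as three concentric spherical shells (brain incl. CSF,
skull, scalp).  For each spherical-harmonic degree ``n`` the radial part of
the potential in every layer is ``A r^n + B r^-(n+1)``; imposing continuity
of potential and of radial current at the two inner interfaces and zero
radial current at the scalp surface yields a small linear system per degree.
The surface gain factors depend only on the head geometry/conductivities and
are cached per head model, so repeated lead-field evaluations (the inner
loop of dipole fitting) stay cheap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "HeadModel",
    "LeadField",
    "best_fit_sphere",
    "make_standard_montage",
    "leadfield",
    "project",
    "homogeneous_sphere_potential",
]


class GeometryError(ValueError):
    """Raised for degenerate electrode/dipole geometry."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ElectrodeMontage:
    """Electrode labels and 3D positions in head frame (RAS mm).

    The head frame has its origin at the fitted sphere center.  ``fiducials``
    maps ``nasion``/``lpa``/``rpa`` to coordinates in the same frame.
    """

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3) mm
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)
    reference: str = "average"
    sphere_center: np.ndarray | None = None
    sphere_radius: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("electrode positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def fit_sphere(self) -> tuple[np.ndarray, float]:
        center, radius = best_fit_sphere(self.positions)
        self.sphere_center, self.sphere_radius = center, radius
        return center, radius


@dataclass(frozen=True)
class HeadModel:
    """Concentric three-shell spherical head.

    Parameters
    ----------
    outer_radius : scalp radius in mm (default 82, a group-average head).
    shell_ratios : outer radius fractions of the brain/skull/scalp
        boundaries, strictly increasing, last equal to 1.
    conductivities : shell conductivities in S/m, inside-out.  Defaults are
        the conventional 0.33 / 0.0042 / 0.33 (skull ~80x more resistive).
    series_order : truncation of the spherical-harmonic expansion.
    """

    outer_radius: float = 82.0
    shell_ratios: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    series_order: int = 100

    def __post_init__(self) -> None:
        r = self.shell_ratios
        if not (0 < r[0] < r[1] < r[2] <= 1.0):
            raise ValueError("shell_ratios must be strictly increasing in (0, 1]")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.series_order < 20:
            raise ValueError("series_order must be >= 20")
        if self.outer_radius <= 0:
            raise ValueError("outer_radius must be positive")

    @property
    def brain_radius(self) -> float:
        return self.outer_radius * self.shell_ratios[0]

    def surface_gains(self, order: int | None = None) -> np.ndarray:
        """Per-degree scalp-surface gain g_n (n = 1..order).

        g_n multiplies the degree-n coefficient of the primary (infinite
        medium) dipole potential, normalized so that a homogeneous sphere
        (equal conductivities) gives g_n = (2n+1)/n.
        """
        order = self.series_order if order is None else int(order)
        key = order
        cache = _GAIN_CACHE.setdefault(self, {})
        if key not in cache:
            cache[key] = _shell_gains(self.shell_ratios, self.conductivities, order)
        return cache[key]


_GAIN_CACHE: dict[HeadModel, dict[int, np.ndarray]] = {}


@dataclass
class LeadField:
    """Linear gain (channels × 3) from dipole moment (nA·m) to scalp µV."""

    gains: np.ndarray
    dipole_position: np.ndarray
    montage_ref: str = ""
    head_model_ref: str = ""


# --------------------------------------------------------------------------
# sphere fitting
# --------------------------------------------------------------------------


def best_fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through a cloud of 3D points.

    Uses the algebraic (linear) solution as a starting point, then refines
    center and radius with Gauss-Newton on the true radial residuals
    ``|p_i - c| - r``.

    Raises
    ------
    GeometryError
        If fewer than 4 points are given or the points are (nearly)
        coplanar/coincident, so no unique sphere exists.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise GeometryError("need at least 4 points of shape (n, 3)")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise GeometryError("points are coplanar or coincident; sphere is not unique")

    # algebraic fit: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))

    # Gauss-Newton refinement of geometric residuals
    for _ in range(50):
        diff = pts - center
        dist = np.linalg.norm(diff, axis=1)
        resid = dist - radius
        J = np.hstack([-diff / dist[:, None], -np.ones((len(pts), 1))])
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        center = center + step[:3]
        radius = float(radius + step[3])
        if np.linalg.norm(step) < 1e-12:
            break
    return center, radius


# --------------------------------------------------------------------------
# standard montage
# --------------------------------------------------------------------------

_STANDARD_64 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "M1", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "M2",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "PO9", "PO10",
]


def _homologue(label: str) -> str | None:
    """Left/right partner of a 10-10 label (O1 -> O2), None for midline."""
    m = re.match(r"^([A-Za-z]+)(\d+)$", label)
    if m is None:
        return None
    base, num = m.group(1), int(m.group(2))
    partner = num + 1 if num % 2 == 1 else num - 1
    return f"{base}{partner}"


def make_standard_montage(
    system: str = "10-10",
    n_channels: int = 64,
    outer_radius: float = 82.0,
) -> ElectrodeMontage:
    """Deterministic 64-channel 10-10 montage on a sphere.

    Positions start from the published 10-10/10-5 layout (via MNE's standard
    montage table), are projected radially onto the fitted sphere scaled to
    ``outer_radius``, and homologous left/right pairs are symmetrized across
    the sagittal plane so the montage is exactly mirror-symmetric.
    """
    if system not in ("10-10", "10-20"):
        raise ValueError(f"unsupported montage system {system!r}")
    if n_channels != 64:
        raise ValueError("only the 64-channel variant is provided")

    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    missing = [lab for lab in _STANDARD_64 if lab not in ch_pos]
    if missing:
        raise RuntimeError(f"standard montage lacks labels: {missing}")
    pos = np.array([ch_pos[lab] for lab in _STANDARD_64]) * 1000.0  # m -> mm

    center, _ = best_fit_sphere(pos)
    pos = pos - center
    # radial projection to the target sphere
    pos = pos * (outer_radius / np.linalg.norm(pos, axis=1))[:, None]

    # exact sagittal symmetry: average each label with its mirrored homologue
    idx = {lab: i for i, lab in enumerate(_STANDARD_64)}
    sym = pos.copy()
    for lab, i in idx.items():
        partner = _homologue(lab)
        if partner is None:
            sym[i, 0] = 0.0
        else:
            j = idx[partner]
            mirrored = pos[j] * np.array([-1.0, 1.0, 1.0])
            sym[i] = 0.5 * (pos[i] + mirrored)
    sym = sym * (outer_radius / np.linalg.norm(sym, axis=1))[:, None]
    # exact zero on the midline after renormalization
    for lab, i in idx.items():
        if _homologue(lab) is None:
            sym[i, 0] = 0.0
            sym[i] = sym[i] * (outer_radius / np.linalg.norm(sym[i]))

    fid = std.get_positions()
    fiducials = {}
    for name, key in (("nasion", "nasion"), ("lpa", "lpa"), ("rpa", "rpa")):
        v = fid[key]
        if v is not None:
            fiducials[name] = np.asarray(v) * 1000.0 - center

    montage = ElectrodeMontage(
        labels=list(_STANDARD_64),
        positions=sym,
        fiducials=fiducials,
        reference="average",
        sphere_center=np.zeros(3),
        sphere_radius=float(outer_radius),
    )
    return montage


# --------------------------------------------------------------------------
# three-shell analytic solution
# --------------------------------------------------------------------------


def _shell_gains(
    ratios: tuple[float, float, float],
    sigmas: tuple[float, float, float],
    order: int,
) -> np.ndarray:
    """Surface gain g_n for degrees 1..order (normalized radius).

    The degree-n primary potential of the dipole in the innermost layer is
    written c_n / r^(n+1) (r in units of the scalp radius).  In each layer
    the full potential is A r^n + B r^-(n+1); boundary conditions give a
    5x5 system whose solution evaluated at r=1 defines g_n = V_surface/c_n.
    """
    f1, f2, _ = ratios
    s1, s2, s3 = sigmas
    gains = np.empty(order)
    for i, n in enumerate(range(1, order + 1)):
        np1 = n + 1
        # unknowns: A1, A2, B2, A3, B3  (c_n = 1)
        M = np.array(
            [
                # potential continuity at f1
                [f1**n, -(f1**n), -(f1 ** -np1), 0.0, 0.0],
                # current continuity at f1
                [
                    s1 * n * f1 ** (n - 1),
                    -s2 * n * f1 ** (n - 1),
                    s2 * np1 * f1 ** -(n + 2),
                    0.0,
                    0.0,
                ],
                # potential continuity at f2
                [0.0, f2**n, f2 ** -np1, -(f2**n), -(f2 ** -np1)],
                # current continuity at f2
                [
                    0.0,
                    s2 * n * f2 ** (n - 1),
                    -s2 * np1 * f2 ** -(n + 2),
                    -s3 * n * f2 ** (n - 1),
                    s3 * np1 * f2 ** -(n + 2),
                ],
                # zero radial current at the scalp surface
                [0.0, 0.0, 0.0, n, -np1],
            ]
        )
        rhs = np.array(
            [
                -(f1 ** -np1),
                s1 * np1 * f1 ** -(n + 2),
                0.0,
                0.0,
                0.0,
            ]
        )
        A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
        gains[i] = A3 + B3
    return gains


def _legendre_terms(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n'(x) for n = 1..order, stacked (order, len(x))."""
    x = np.asarray(x, dtype=float)
    P = np.empty((order + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0] = 1.0
    dP[0] = 0.0
    P[1] = x
    dP[1] = 1.0
    for n in range(1, order):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P[1:], dP[1:]


def leadfield(
    head: HeadModel,
    montage: ElectrodeMontage,
    position: np.ndarray,
    check_convergence: bool = True,
) -> LeadField:
    """Analytic three-shell lead field of a dipole at ``position`` (mm).

    Returns the channels × 3 gain matrix: potential in µV per unit moment
    (1 nA·m) along x, y, z.  Raises :class:`GeometryError` if the dipole is
    not strictly inside the brain compartment, and ``ValueError`` if the
    truncated series has not converged at the requested order.
    """
    position = np.asarray(position, dtype=float)
    R = head.outer_radius
    b = float(np.linalg.norm(position))
    if b >= head.brain_radius:
        raise GeometryError(
            f"dipole at radius {b:.1f} mm is outside the brain shell "
            f"({head.brain_radius:.1f} mm)"
        )
    order = head.series_order
    g = head.surface_gains(order)

    e_dir = montage.positions / np.linalg.norm(montage.positions, axis=1)[:, None]
    t = b / R
    if b < 1e-9:
        zhat = np.array([0.0, 0.0, 1.0])
    else:
        zhat = position / b
    x = e_dir @ zhat  # cos(gamma) per electrode
    x = np.clip(x, -1.0, 1.0)
    e_perp = e_dir - x[:, None] * zhat[None, :]

    n_arr = np.arange(1, order + 1, dtype=float)
    tn = t ** (n_arr - 1)  # t^(n-1)

    P, dP = _legendre_terms(x, order)  # (order, n_elec)
    w = g * tn  # (order,)
    rad = (w * n_arr) @ P  # (n_elec,) radial angular sum
    tan = w @ dP  # (n_elec,) tangential angular sum

    if check_convergence and order > 12:
        # contribution of the last 10 retained degrees, relative to the sum
        w_tail = w[-10:]
        n_tail = n_arr[-10:]
        rad_tail = (w_tail * n_tail) @ P[-10:]
        tan_tail = w_tail @ dP[-10:]
        num = np.hypot(rad_tail, tan_tail).max()
        den = max(np.hypot(rad, tan).max(), 1e-300)
        if num > 1e-8 * den:
            raise ValueError(
                f"series not converged at order {order} for eccentricity {t:.3f}; "
                "increase series_order"
            )

    K = 1000.0 / (4.0 * np.pi * head.conductivities[0] * R**2)
    # gains[e, :] = K * (rad_e * zhat + tan_e * e_perp_e)
    gains = K * (rad[:, None] * zhat[None, :] + tan[:, None] * e_perp)
    return LeadField(
        gains=gains,
        dipole_position=position.copy(),
        montage_ref=f"{montage.n_channels}ch",
        head_model_ref=f"3shell-R{R:g}",
    )


def project(lead: LeadField, moment_series: np.ndarray) -> np.ndarray:
    """Scalp potentials (channels × time) of a dipole moment time series.

    ``moment_series`` is (time, 3) or (3,) in nA·m; output is µV.
    """
    m = np.asarray(moment_series, dtype=float)
    if m.ndim == 1:
        if m.shape != (3,):
            raise ValueError("single moment must have 3 components")
        return lead.gains @ m
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("moment_series must be (time, 3)")
    return lead.gains @ m.T


# --------------------------------------------------------------------------
# homogeneous sphere closed form (reference solution)
# --------------------------------------------------------------------------


def homogeneous_sphere_potential(
    position: np.ndarray,
    moment: np.ndarray,
    electrode_positions: np.ndarray,
    radius: float,
    conductivity: float = 0.33,
) -> np.ndarray:
    """Closed-form scalp potential of a dipole in a homogeneous sphere.

    The infinite Legendre series for the bounded homogeneous sphere sums in
    closed form (generating-function identities), giving an expression in
    the chord distance only.  Units as in :func:`leadfield`: mm, nA·m, µV.
    Used as the analytic reference for the shell series with equal
    conductivities.
    """
    r0 = np.asarray(position, dtype=float)
    q = np.asarray(moment, dtype=float)
    elec = np.asarray(electrode_positions, dtype=float)
    R = float(radius)
    b = float(np.linalg.norm(r0))
    if b >= R:
        raise GeometryError("dipole must be inside the sphere")
    e_dir = elec / np.linalg.norm(elec, axis=1)[:, None]
    t = b / R
    zhat = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    x = np.clip(e_dir @ zhat, -1.0, 1.0)
    e_perp = e_dir - x[:, None] * zhat[None, :]

    chi = np.sqrt(1.0 - 2.0 * t * x + t * t)
    if t > 1e-8:
        F_rad = (2.0 * t * (x - t) / chi**3 + 1.0 / chi - 1.0) / t
    else:
        F_rad = 3.0 * x + t * (7.5 * x**2 - 2.5)  # small-t expansion
    F_tan = 2.0 / chi**3 + (chi + 1.0) / (chi * (1.0 - t * x + chi))

    K = 1000.0 / (4.0 * np.pi * conductivity * R**2)
    return K * (F_rad * (zhat @ q) + F_tan * (e_perp @ q))
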