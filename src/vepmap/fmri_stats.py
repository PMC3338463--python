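"""Voxelwise fMRI statistics.

Two analysis paths:

* **Phase-encoded (retinotopy)** — per-voxel Fourier analysis at the
  stimulus frequency: an F ratio between signal power at the stimulus bin
  and mean power at all other non-DC bins (excluding the second and third
  harmonics), with the response phase mapping to polar angle or
  eccentricity, and the visual field sign computed from the gradients of
  the two retinotopic coordinate maps.

* **Block design** — ordinary least squares with a boxcar convolved with a
  canonical double-gamma HRF plus constant and linear-drift confounds, with
  cluster-size inference by sign-flip permutation of the reduced-model
  residuals (a distribution-free stand-in for Gaussian-random-field
  cluster correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "VolumeSeries",
    "DesignSpec",
    "SpectralStatMap",
    "StatMap",
    "ClusterSet",
    "canonical_hrf",
    "fourier_stats",
    "phase_to_retinotopy",
    "field_sign",
    "glm_block",
    "cluster_threshold",
]


@dataclass
class VolumeSeries:
    """4D BOLD series (x, y, z, t) with scan timing and spatial metadata."""

    data: np.ndarray
    tr: float = 2.0
    affine: np.ndarray = None
    voxel_size_mm: float = 3.0
    n_discarded_initial: int = 4

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("volume series must be 4D (x, y, z, t)")
        if self.affine is None:
            self.affine = np.diag(
                [self.voxel_size_mm, self.voxel_size_mm, self.voxel_size_mm, 1.0]
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class DesignSpec:
    """Stimulation design timing.

    Block designs alternate ``on_s`` seconds of stimulation with ``off_s``
    of rest for ``n_cycles`` cycles (defaults 16/16 s × 8).  Periodic
    phase-encoded designs sweep one stimulus cycle every ``cycle_s`` seconds
    for ``n_cycles`` cycles per scan (defaults 64 s × 8).
    """

    kind: str = "block"  # "block" | "periodic"
    on_s: float = 16.0
    off_s: float = 16.0
    n_cycles: int = 8
    cycle_s: float = 64.0
    tr: float = 2.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0

    @property
    def n_volumes(self) -> int:
        if self.kind == "block":
            return int(round(self.n_cycles * (self.on_s + self.off_s) / self.tr))
        return int(round(self.n_cycles * self.cycle_s / self.tr))

    @property
    def stimulus_bin(self) -> int:
        return self.n_cycles

    def boxcar(self) -> np.ndarray:
        if self.kind != "block":
            raise ValueError("boxcar is defined for block designs")
        t = np.arange(self.n_volumes) * self.tr
        period = self.on_s + self.off_s
        return ((t % period) < self.on_s).astype(float)


def canonical_hrf(
    tr: float = 2.0,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Gamma densities with unit dispersion peaking at ``peak_s`` (response)
    and ``undershoot_s`` (undershoot, scaled by ``ratio``), normalized to
    unit peak.
    """
    t = np.arange(0.0, duration_s + tr / 2, tr)
    h = stats.gamma.pdf(t, peak_s) - ratio * stats.gamma.pdf(t, undershoot_s)
    return h / h.max()


# --------------------------------------------------------------------------
# Fourier (phase-encoded) analysis
# --------------------------------------------------------------------------


@dataclass
class SpectralStatMap:
    """Per-voxel F, p, amplitude and phase at the stimulus frequency."""

    F: np.ndarray
    p: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray  # radians in (-pi, pi]
    df: tuple[int, int]
    stimulus_bin: int


def fourier_stats(series: VolumeSeries, design: DesignSpec) -> SpectralStatMap:
    """F ratio of signal power at the stimulus frequency vs other bins.

    Signal power is taken at the DFT bin equal to cycles/scan; the noise
    band is every other bin excluding DC, the Nyquist bin and the second
    and third harmonics.  With white noise the statistic follows
    F(2, 2·n_noise_bins); an exactly noise-free voxel is reported as +inf.
    """
    N = series.n_volumes
    if N != design.n_volumes:
        raise ValueError(
            f"series has {N} volumes but design specifies {design.n_volumes}"
        )
    k = design.stimulus_bin
    X = np.fft.rfft(series.data, axis=3)
    power = np.abs(X) ** 2

    n_bins = X.shape[3]  # N//2 + 1
    noise_mask = np.ones(n_bins, dtype=bool)
    noise_mask[0] = False  # DC
    if N % 2 == 0:
        noise_mask[-1] = False  # Nyquist
    for h in (k, 2 * k, 3 * k):
        if h < n_bins:
            noise_mask[h] = False
    n_noise = int(noise_mask.sum())

    sig = power[..., k]
    noise = power[..., noise_mask].mean(axis=3)
    # noise power at rounding-error level relative to the signal is treated
    # as zero: an exactly periodic voxel gets the +inf sentinel
    negligible = noise <= 1e-12 * sig
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(~negligible, sig / np.where(~negligible, noise, 1.0), np.inf)
        F = np.where(negligible & (sig == 0), 0.0, F)
    df = (2, 2 * n_noise)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 0, F), *df))
    phase = np.angle(X[..., k])
    amplitude = 2.0 * np.abs(X[..., k]) / N
    return SpectralStatMap(F=F, p=p, amplitude=amplitude, phase=phase, df=df,
                           stimulus_bin=k)


def phase_to_retinotopy(
    phase: np.ndarray,
    design: DesignSpec,
    hemodynamic_delay_s: float = 5.0,
    sweep: tuple[float, float] = (0.0, 360.0),
    direction: int = 1,
) -> np.ndarray:
    """Map response phase to the retinotopic coordinate swept by the cycle.

    The hemodynamic delay is subtracted as a phase offset, the remaining
    phase is read as the cycle fraction at which the stimulus crossed the
    voxel's preferred coordinate, and that fraction interpolates linearly
    from ``sweep[0]`` to ``sweep[1]``.  ``direction=-1`` reverses the sweep
    (mirror-reversed stimulus progression).
    """
    if not 0 <= hemodynamic_delay_s < design.cycle_s:
        raise ValueError("hemodynamic delay must lie within one cycle")
    frac = (-np.asarray(phase) / (2 * np.pi)) - hemodynamic_delay_s / design.cycle_s
    if direction == -1:
        frac = -frac
    frac = np.mod(frac, 1.0)
    return sweep[0] + frac * (sweep[1] - sweep[0])


def field_sign(
    polar_map: np.ndarray,
    ecc_map: np.ndarray,
    F: np.ndarray | None = None,
    f_threshold: float = 0.0,
    grad_tol: float = 1e-9,
) -> np.ndarray:
    """Visual field sign from retinotopic coordinate gradients.

    Sign of the z component of the cross product of the polar-angle and
    eccentricity gradients over the (flattened-cortex) lattice, by central
    differences: +1 where polar angle increases along +x while eccentricity
    increases along +y (mirror-image convention), -1 for the non-mirror
    arrangement, 0 where F is below threshold or a gradient degenerates.
    """
    if polar_map.shape != ecc_map.shape:
        raise ValueError("maps must share a lattice")
    dp_dx, dp_dy = np.gradient(polar_map)
    de_dx, de_dy = np.gradient(ecc_map)
    cross = dp_dx * de_dy - dp_dy * de_dx
    out = np.sign(cross).astype(int)
    gp = np.hypot(dp_dx, dp_dy)
    ge = np.hypot(de_dx, de_dy)
    out[(gp < grad_tol) | (ge < grad_tol)] = 0
    if F is not None:
        out[F < f_threshold] = 0
    return out


# --------------------------------------------------------------------------
# block-design GLM
# --------------------------------------------------------------------------


@dataclass
class StatMap:
    """Per-voxel t statistic for the task regressor, with effect size."""

    t: np.ndarray
    beta: np.ndarray
    df: int
    p: np.ndarray
    affine: np.ndarray = None
    design_matrix: np.ndarray = None


def _design_matrix(design: DesignSpec) -> np.ndarray:
    box = design.boxcar()
    hrf = canonical_hrf(
        design.tr,
        peak_s=design.hrf_peak_s,
        undershoot_s=design.hrf_undershoot_s,
        ratio=design.hrf_ratio,
    )
    task = np.convolve(box, hrf)[: len(box)]
    n = len(box)
    drift = np.linspace(-1, 1, n)
    return np.column_stack([task, np.ones(n), drift])


def glm_block(series: VolumeSeries, design: DesignSpec) -> StatMap:
    """OLS fit of [boxcar⊗HRF, constant, linear drift] per voxel.

    Returns the t statistic of the task regressor with df = T - 3.  The t
    statistic is scale-free (invariant to affine rescaling of the series).
    """
    X = _design_matrix(design)
    n, k = X.shape
    if series.n_volumes != n:
        raise ValueError(f"series has {series.n_volumes} volumes, design {n}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    shape3 = series.data.shape[:3]
    Y = series.data.reshape(-1, n).T  # (time, voxels)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - k
    sigma2 = np.sum(resid**2, axis=0) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[0] / np.where(se > 0, se, 1.0), 0.0)
    p = stats.t.sf(t, df)  # one-sided: activation
    return StatMap(
        t=t.reshape(shape3),
        beta=beta[0].reshape(shape3),
        df=df,
        p=p.reshape(shape3),
        affine=series.affine,
        design_matrix=X,
    )


# --------------------------------------------------------------------------
# cluster inference
# --------------------------------------------------------------------------

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ClusterSet:
    """Connected suprathreshold components with permutation p-values."""

    clusters: list[dict]
    affine: np.ndarray
    voxel_p: float
    cluster_p: float | None
    t_threshold: float
    null_max_sizes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "label": c["id"],
                "size_voxels": c["size"],
                "peak_stat": c["peak_stat"],
                "x_mm": c["centroid_mm"][0],
                "y_mm": c["centroid_mm"][1],
                "z_mm": c["centroid_mm"][2],
                "p_cluster": c.get("p", np.nan),
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows)


def _label_clusters(tmap: np.ndarray, thr: float, min_size: int = 1) -> list[dict]:
    mask = tmap > thr
    labels, n = ndimage.label(mask, structure=_CONN6)
    out = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_size:
            continue
        vals = tmap[labels == lab]
        peak_idx = vox[np.argmax(vals)]
        out.append(
            {
                "id": len(out) + 1,
                "voxels": vox,
                "size": int(len(vox)),
                "peak_stat": float(vals.max()),
                "peak_ijk": peak_idx,
            }
        )
    return out


def cluster_threshold(
    statmap: StatMap,
    voxel_p: float = 0.001,
    cluster_p: float | None = 0.001,
    n_perm: int = 1000,
    series: VolumeSeries | None = None,
    design: DesignSpec | None = None,
    min_cluster_size: int = 1,
    seed: int = 0,
) -> ClusterSet:
    """Cluster-level inference on a voxelwise t map.

    Voxels with one-sided p below ``voxel_p`` are kept and grouped into
    6-connected components.  If the originating ``series`` and ``design``
    are supplied, a max-cluster-size null is built by sign-flipping the
    reduced-model (confound-only) residuals ``n_perm`` times; clusters with
    family-wise p above ``cluster_p`` are dropped.  Without a series, all
    suprathreshold clusters of at least ``min_cluster_size`` voxels are
    returned descriptively (p = NaN).
    """
    thr = float(stats.t.isf(voxel_p, statmap.df))
    clusters = _label_clusters(statmap.t, thr, min_cluster_size)

    null_sizes = None
    if cluster_p is not None and series is not None:
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if design is None:
            raise ValueError("permutation mode needs the design")
        X = _design_matrix(design)
        n = X.shape[0]
        shape3 = series.data.shape[:3]
        Y = series.data.reshape(-1, n).T
        X0 = X[:, 1:]  # confounds only
        beta0 = np.linalg.pinv(X0) @ Y
        fit0 = X0 @ beta0
        e = Y - fit0
        pinv = np.linalg.pinv(X)
        XtX_inv00 = np.linalg.inv(X.T @ X)[0, 0]
        df = n - X.shape[1]
        norm_Y0 = np.sum(fit0**2, axis=0)
        norm_e = np.sum(e**2, axis=0)
        tot = norm_Y0 + norm_e  # sign flips leave ||Y*||^2 unchanged
        XtX = X.T @ X

        rng = np.random.default_rng(seed)
        null_sizes = np.zeros(n_perm, dtype=int)
        for pidx in range(n_perm):
            s = rng.choice([-1.0, 1.0], size=n)
            Yp = fit0 + s[:, None] * e
            beta = pinv @ Yp
            rss = tot - np.einsum("kv,kj,jv->v", beta, XtX, beta)
            sigma2 = np.maximum(rss, 0.0) / df
            se = np.sqrt(np.maximum(sigma2 * XtX_inv00, 1e-300))
            tmap = (beta[0] / se).reshape(shape3)
            labs, nlab = ndimage.label(tmap > thr, structure=_CONN6)
            if nlab:
                null_sizes[pidx] = np.bincount(labs.ravel())[1:].max()

        kept = []
        for c in clusters:
            p_c = (1 + np.sum(null_sizes >= c["size"])) / (n_perm + 1)
            c = dict(c, p=float(p_c))
            if p_c <= cluster_p:
                kept.append(c)
        clusters = kept
        for i, c in enumerate(clusters, 1):
            c["id"] = i

    A = statmap.affine if statmap.affine is not None else np.eye(4)
    for c in clusters:
        centroid_vox = np.asarray(c["voxels"], dtype=float).mean(axis=0)
        c["centroid_mm"] = (A @ np.append(centroid_vox, 1.0))[:3]
    return ClusterSet(
        clusters=clusters,
        affine=A,
        voxel_p=voxel_p,
        cluster_p=cluster_p,
        t_threshold=thr,
        null_max_sizes=null_sizes,
        meta={"n_perm": n_perm if null_sizes is not None else 0, "seed": seed},
    )
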