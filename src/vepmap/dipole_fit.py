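"""Equivalent-current-dipole source analysis of averaged VEPs.

The model is a small ordered set of fixed-position, fixed-orientation
dipoles.  Each dipole is fit in a component-specific latency window by
minimizing a compound cost

    cost = 0.8 * RV + 0.2 * energy

where RV is the percent residual variance between the forward-modelled and
observed spatio-temporal scalp distribution, and the energy term is a
normalized source-power penalty that discourages large, mutually cancelling
moments (interacting dipoles).  Fitting is sequential: dipoles explaining
earlier waveform portions stay frozen while later ones are added.  Fitted
models can then be seeded — positions snapped to fMRI activation centroids —
and refit in orientation only.

Given a candidate position, the optimal orientation is available in closed
form: after projecting out the frozen dipoles' fields, the unit moment
direction maximizing explained variance solves a 3x3 generalized eigenvalue
problem.  The nonlinear search therefore runs over position only
(multi-start Nelder-Mead on a posterior-brain lattice plus seeded random
starts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize, stats

from .forward_model import ElectrodeMontage, HeadModel, leadfield
from .vep_pipeline import EvokedResponse

__all__ = [
    "DipoleSource",
    "FitWindow",
    "SourceModel",
    "residual_variance",
    "source_waveforms",
    "energy_term",
    "compound_cost",
    "fit_dipole",
    "fit_sequential",
    "seed_refit_orientation",
    "rot_test",
    "default_windows",
]


@dataclass
class DipoleSource:
    """A fixed dipole: position (head-frame mm) and unit orientation."""

    position: np.ndarray
    orientation: np.ndarray
    label: str = ""
    position_fixed: bool = True
    orientation_fixed: bool = True
    seed_roi: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(self.orientation)
        if abs(nrm - 1.0) > 1e-6:
            if nrm == 0:
                raise ValueError("orientation must be a nonzero vector")
            self.orientation = self.orientation / nrm


@dataclass(frozen=True)
class FitWindow:
    """Latency window over which one dipole (or a reused one) is fit."""

    label: str
    start_ms: float
    end_ms: float
    reuse: str | None = None  # label of an earlier dipole to reuse

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")
        if self.reuse is None and not (40.0 <= self.start_ms and self.end_ms <= 350.0):
            raise ValueError(
                f"fitting window {self.label} [{self.start_ms},{self.end_ms}] ms "
                "outside the 40-350 ms optimization range"
            )


def default_windows(speed: str = "slow") -> list[FitWindow]:
    """Component fitting windows for the motion-onset VEP.

    Slow motion: C1 (70-110), P120 (100-140), N160 (140-170), N180
    (170-200), P250 (200-300), and an offset-response window (340-360)
    that reuses the C1 dipole.  Fast motion prepends N70 (60-80).
    """
    slow = [
        FitWindow("C1", 70, 110),
        FitWindow("P120", 100, 140),
        FitWindow("N160", 140, 170),
        FitWindow("N180", 170, 200),
        FitWindow("P250", 200, 300),
        FitWindow("oC1", 340, 360, reuse="C1"),
    ]
    if speed == "slow":
        return slow
    if speed == "fast":
        return [FitWindow("N70", 60, 80)] + slow
    raise ValueError(f"unknown speed {speed!r}")


@dataclass
class SourceModel:
    """Ordered dipole set with waveforms and fit diagnostics."""

    dipoles: list[DipoleSource]
    waveforms: np.ndarray | None  # (n_dipoles, n_times) nA·m
    times_ms: np.ndarray | None
    window_report: list[dict] = field(default_factory=list)
    total_rv: float = 100.0
    total_window_ms: tuple[float, float] = (70.0, 350.0)
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.dipoles]


# --------------------------------------------------------------------------
# cost components
# --------------------------------------------------------------------------


def residual_variance(data: np.ndarray, model: np.ndarray) -> float:
    """Percent of scalp data power unexplained by the model.

    ``100 * sum((data - model)^2) / sum(data^2)`` over channels and samples.
    """
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    if data.shape != model.shape:
        raise ValueError("data and model shapes differ")
    denom = np.sum(data**2)
    if denom == 0:
        raise ValueError("data window is all zero")
    return float(100.0 * np.sum((data - model) ** 2) / denom)


def _avg_ref(x: np.ndarray) -> np.ndarray:
    """Project channels to the average reference (removes the common mode).

    Forward-modelled potentials carry an arbitrary reference while recorded
    data carry the acquisition reference; comparing them is only meaningful
    after both are projected onto the same reference-free subspace.
    """
    return x - x.mean(axis=0, keepdims=True)


def _oriented_gains(
    dipoles: list[DipoleSource], head: HeadModel, montage: ElectrodeMontage
) -> np.ndarray:
    """Stacked oriented lead fields, channels × n_dipoles (µV per nA·m)."""
    if not dipoles:
        return np.zeros((montage.n_channels, 0))
    cols = [
        leadfield(head, montage, d.position).gains @ d.orientation for d in dipoles
    ]
    return _avg_ref(np.column_stack(cols))


def source_waveforms(
    data: np.ndarray,
    dipoles: list[DipoleSource],
    head: HeadModel,
    montage: ElectrodeMontage,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares moment time series for fixed dipoles.

    Returns (n_dipoles, n_times) nA·m.  Raises if the stacked oriented lead
    fields are rank deficient, naming the most collinear dipole pair.
    """
    G = _oriented_gains(dipoles, head, montage) if gains is None else gains
    data = _avg_ref(np.asarray(data, dtype=float))
    if G.shape[1] == 0:
        return np.zeros((0, data.shape[1]))
    norms = np.linalg.norm(G, axis=0)
    if np.any(norms == 0) or np.linalg.matrix_rank(G, tol=1e-8 * norms.max()) < G.shape[1]:
        Gn = G / np.where(norms == 0, 1.0, norms)
        C = np.abs(Gn.T @ Gn)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        li = dipoles[i].label or f"dipole{i}"
        lj = dipoles[j].label or f"dipole{j}"
        raise ValueError(
            f"lead fields are rank deficient; near-collinear pair: {li} and {lj}"
        )
    return np.linalg.lstsq(G, data, rcond=None)[0]


def energy_term(
    waveforms: np.ndarray, data_window: np.ndarray, gains: np.ndarray
) -> float:
    """Source-interaction penalty, on the same percent scale as RV.

    The summed individual scalp power of the dipoles,
    ``sum_d ||g_d||^2 sum_t m_d(t)^2``, in excess of the power the model
    actually radiates, ``sum_t ||sum_d g_d m_d(t)||^2``, normalized by the
    data power (clipped at zero).  A set of non-interacting dipoles scores
    zero; mutually cancelling moments — large individual fields adding up
    to a small scalp field — inflate the term quadratically.
    """
    if waveforms.shape[0] == 0:
        return 0.0
    denom = np.sum(np.asarray(data_window, dtype=float) ** 2)
    if denom == 0:
        raise ValueError("data window is all zero")
    g2 = np.sum(gains**2, axis=0)  # per dipole
    individual = np.sum(g2 * np.sum(waveforms**2, axis=1))
    radiated = np.sum((gains @ waveforms) ** 2)
    return float(100.0 * max(0.0, individual - radiated) / denom)


def compound_cost(
    data_window: np.ndarray,
    dipoles: list[DipoleSource],
    head: HeadModel,
    montage: ElectrodeMontage,
    rv_weight: float = 0.8,
) -> float:
    """0.8·RV + 0.2·energy for the given dipole set on a data window."""
    G = _oriented_gains(dipoles, head, montage)
    Dc = _avg_ref(np.asarray(data_window, dtype=float))
    W = source_waveforms(Dc, dipoles, head, montage, gains=G)
    rv = residual_variance(Dc, G @ W)
    en = energy_term(W, Dc, G)
    return rv_weight * rv + (1.0 - rv_weight) * en


# --------------------------------------------------------------------------
# single-dipole fit
# --------------------------------------------------------------------------


def _best_orientation(A: np.ndarray, Dp: np.ndarray) -> np.ndarray:
    """Unit moment direction maximizing variance explained.

    A is the (prior-projected) 3-column lead field, Dp the projected data.
    Maximizes u'Mu / u'Ku with M = A'Dp Dp'A and K = A'A (3x3 generalized
    eigenproblem).
    """
    M = A.T @ Dp @ Dp.T @ A
    K = A.T @ A
    K = K + 1e-12 * np.trace(K) * np.eye(3)
    w, V = linalg.eigh(M, K)
    u = V[:, -1]
    return u / np.linalg.norm(u)


def _window_slice(evoked: EvokedResponse, window: FitWindow) -> np.ndarray:
    times = evoked.times_ms
    return (times >= window.start_ms) & (times <= window.end_ms)


class _WindowCost:
    """Compound cost of adding one free-position dipole to frozen priors."""

    def __init__(
        self,
        D: np.ndarray,
        prior_gains: np.ndarray,
        head: HeadModel,
        montage: ElectrodeMontage,
        rv_weight: float = 0.8,
    ) -> None:
        self.D = _avg_ref(D)
        self.head = head
        self.montage = montage
        self.rv_weight = rv_weight
        self.data_power = float(np.sum(self.D**2))
        self.Gp = prior_gains
        if prior_gains.shape[1]:
            self.Q = np.linalg.qr(prior_gains)[0]
            self.Dp = self.D - self.Q @ (self.Q.T @ self.D)
        else:
            self.Q = None
            self.Dp = self.D
        self.max_radius = 0.90 * head.brain_radius
        self.n_evals = 0

    def orientation_at(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        L = _avg_ref(leadfield(self.head, self.montage, pos,
                                check_convergence=False).gains)
        A = L if self.Q is None else L - self.Q @ (self.Q.T @ L)
        return _best_orientation(A, self.Dp), L

    def cost_at(self, pos: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_evals += 1
        r = np.linalg.norm(pos)
        if r >= self.max_radius:
            # pull back inside and add a steep penalty so the search returns
            pos = pos * (self.max_radius * 0.999 / r)
            penalty = 1e3 * (r - self.max_radius)
        else:
            penalty = 0.0
        u, L = self.orientation_at(pos)
        G = np.column_stack([self.Gp, L @ u])
        W = np.linalg.lstsq(G, self.D, rcond=None)[0]
        resid = self.D - G @ W
        rv = 100.0 * np.sum(resid**2) / self.data_power
        g2 = np.sum(G**2, axis=0)
        individual = np.sum(g2 * np.sum(W**2, axis=1))
        radiated = np.sum((G @ W) ** 2)
        en = 100.0 * max(0.0, individual - radiated) / self.data_power
        return self.rv_weight * rv + (1 - self.rv_weight) * en + penalty, u

    def __call__(self, pos: np.ndarray) -> float:
        return self.cost_at(pos)[0]


def _start_points(head: HeadModel, rng: np.random.Generator, n_random: int) -> np.ndarray:
    """Deterministic posterior-brain lattice plus seeded random starts."""
    r = head.brain_radius
    lattice = np.array(
        [
            [sx * 0.35 * r, sy, sz * r]
            for sx in (-1, 1)
            for sy in (-0.75 * r, -0.35 * r)
            for sz in (0.05, 0.45)
        ]
    )
    rand = []
    while len(rand) < n_random:
        p = rng.uniform(-1, 1, 3) * r
        if np.linalg.norm(p) < 0.85 * r and p[1] < 0:
            rand.append(p)
    return np.vstack([lattice, np.array(rand)]) if n_random else lattice


def fit_dipole(
    evoked: EvokedResponse,
    window: FitWindow,
    fixed_prior: list[DipoleSource],
    head: HeadModel,
    montage: ElectrodeMontage,
    seed: int = 0,
    n_random_starts: int = 4,
    max_iter: int = 200,
    fatol: float = 1e-6,
) -> tuple[DipoleSource, dict]:
    """Fit one dipole's position and orientation over a latency window.

    Prior dipoles keep their geometry; their waveforms are co-estimated.
    Multi-start search: 8 deterministic posterior-brain starts plus
    ``n_random_starts`` seeded random starts, each polished locally; the
    winner (lowest cost, then lowest eccentricity) is refined once more at
    tight tolerance.  Returns the dipole and a diagnostics dict.
    """
    mask = _window_slice(evoked, window)
    if not mask.any():
        raise ValueError(f"window {window.label} outside epoch")
    D = _avg_ref(evoked.data[:, mask])
    if np.sum(D**2) == 0:
        raise ValueError(f"data window {window.label} is all zero")

    Gp = _oriented_gains(fixed_prior, head, montage)
    costf = _WindowCost(D, Gp, head, montage)
    rng = np.random.default_rng(seed)
    starts = _start_points(head, rng, n_random_starts)

    results = []
    for p0 in starts:
        res = optimize.minimize(
            costf,
            p0,
            method="Nelder-Mead",
            options={"maxiter": max_iter, "fatol": 1e-3, "xatol": 0.05},
        )
        results.append(res)
    order = sorted(
        range(len(results)),
        key=lambda i: (results[i].fun, np.linalg.norm(results[i].x)),
    )
    best = results[order[0]]
    polish = optimize.minimize(
        costf,
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 2 * max_iter, "fatol": fatol, "xatol": 1e-4},
    )
    if not (polish.success or best.success):
        raise RuntimeError(
            f"dipole fit did not converge in window {window.label}: {polish.message}"
        )
    pos = polish.x
    cost, u = costf.cost_at(pos)

    dip = DipoleSource(position=pos, orientation=u, label=window.label)
    # orient so the window moment waveform peaks positive (sign convention)
    g_new = _avg_ref(
        (leadfield(head, montage, pos).gains @ dip.orientation)[:, None]
    )[:, 0]
    G = np.column_stack([Gp, g_new])
    W = np.linalg.lstsq(G, D, rcond=None)[0]
    w_new = W[-1]
    if w_new[np.argmax(np.abs(w_new))] < 0:
        dip.orientation = -dip.orientation
        W[-1] = -w_new
    model = G @ W
    rv = residual_variance(D, model)
    diag = {
        "window": window.label,
        "rv": rv,
        "cost": cost,
        "n_evals": costf.n_evals,
        "n_starts": len(starts),
        "seed": seed,
        "converged": bool(polish.success or best.success),
    }
    return dip, diag


# --------------------------------------------------------------------------
# sequential fitting
# --------------------------------------------------------------------------


def fit_sequential(
    evoked: EvokedResponse,
    windows: list[FitWindow],
    head: HeadModel,
    montage: ElectrodeMontage,
    seed: int = 0,
    total_window_ms: tuple[float, float] = (70.0, 350.0),
    **fit_kwargs,
) -> SourceModel:
    """Window-by-window sequential dipole fitting.

    Earlier dipoles are left in place as later ones are added.  Windows with
    ``reuse`` set add no dipole; they re-report RV for an existing one.  On
    a per-window failure the partial model is returned with the failure
    flagged in the window report.
    """
    if windows and any(
        windows[i].start_ms > windows[i + 1].start_ms for i in range(len(windows) - 1)
    ):
        raise ValueError("windows must be ordered by start time")

    dipoles: list[DipoleSource] = []
    report: list[dict] = []
    for k, win in enumerate(windows):
        if win.reuse is not None:
            if win.reuse not in [d.label for d in dipoles]:
                report.append(
                    {"window": win.label, "error": f"no dipole {win.reuse!r} to reuse"}
                )
                continue
            mask = _window_slice(evoked, win)
            D = _avg_ref(evoked.data[:, mask])
            G = _oriented_gains(dipoles, head, montage)
            W = source_waveforms(D, dipoles, head, montage, gains=G)
            report.append(
                {
                    "window": win.label,
                    "reuse": win.reuse,
                    "rv": residual_variance(D, G @ W),
                    "converged": True,
                }
            )
            continue
        # skip windows with no unexplained signal left (fitting a source to
        # numerical residue only splits moments across collinear lead fields)
        mask = _window_slice(evoked, win)
        D = _avg_ref(evoked.data[:, mask])
        if dipoles:
            Gp = _oriented_gains(dipoles, head, montage)
            Q = np.linalg.qr(Gp)[0]
            D = D - Q @ (Q.T @ D)
        epoch_power = float(np.sum(_avg_ref(evoked.data) ** 2))
        if np.sum(D**2) < 1e-8 * epoch_power:
            report.append(
                {"window": win.label, "skipped_low_power": True, "converged": True}
            )
            continue
        try:
            dip, diag = fit_dipole(
                evoked, win, dipoles, head, montage, seed=seed + k, **fit_kwargs
            )
        except (ValueError, RuntimeError) as exc:
            report.append({"window": win.label, "error": str(exc), "converged": False})
            continue
        dipoles.append(dip)
        report.append(diag)

    times = evoked.times_ms
    if dipoles:
        W_full = source_waveforms(evoked.data, dipoles, head, montage)
        tot_mask = (times >= total_window_ms[0]) & (times <= total_window_ms[1])
        G = _oriented_gains(dipoles, head, montage)
        total_rv = residual_variance(
            _avg_ref(evoked.data)[:, tot_mask], (G @ W_full)[:, tot_mask]
        )
    else:
        W_full = np.zeros((0, len(times)))
        total_rv = 100.0
    return SourceModel(
        dipoles=dipoles,
        waveforms=W_full,
        times_ms=times,
        window_report=report,
        total_rv=total_rv,
        total_window_ms=total_window_ms,
        meta={"seed": seed, "windows": [(w.label, w.start_ms, w.end_ms) for w in windows]},
    )


def seed_refit_orientation(
    model: SourceModel,
    rois,
    evoked: EvokedResponse,
    head: HeadModel,
    montage: ElectrodeMontage,
    windows: list[FitWindow] | None = None,
) -> SourceModel:
    """Snap dipoles to their nearest fMRI ROI and refit orientation only.

    ``rois`` is a :class:`~vepmap.coregister.ROITable` (or DataFrame with
    ``label, x_mm, y_mm, z_mm`` columns).  Every dipole position is replaced
    by its matched ROI centroid; orientations are re-optimized per original
    fitting window with all other dipoles frozen.  The window report gains
    ``rv_before``/``rv_after`` columns, mirroring the per-window RV-max
    reporting convention of seeded source analyses.
    """
    from .coregister import match_nearest_roi

    if len(getattr(rois, "table", rois)) == 0:
        raise ValueError("ROI table is empty")
    if windows is None:
        windows = [
            FitWindow(w[0], w[1], w[2]) for w in model.meta.get("windows", [])
            if w[0] in model.labels
        ]
    win_by_label = {w.label: w for w in windows}

    seeded = [
        replace(
            d,
            position=d.position.copy(),
            orientation=d.orientation.copy(),
        )
        for d in model.dipoles
    ]
    matches = {}
    for d in seeded:
        row = match_nearest_roi(d.position, rois)
        d.position = np.array([row["x_mm"], row["y_mm"], row["z_mm"]])
        d.seed_roi = row["label"]
        matches[d.label] = row

    # orientation refits are coupled through the joint waveform estimate, so
    # cycle over the dipoles until the orientations stabilize
    leads = {d.label: _avg_ref(leadfield(head, montage, d.position).gains)
             for d in seeded}
    for _ in range(20):
        max_change = 0.0
        for i, d in enumerate(seeded):
            win = win_by_label.get(d.label)
            if win is None:
                continue
            mask = _window_slice(evoked, win)
            D = _avg_ref(evoked.data[:, mask])
            others = seeded[:i] + seeded[i + 1 :]
            Gp = _oriented_gains(others, head, montage)
            L = leads[d.label]
            if Gp.shape[1]:
                Q = np.linalg.qr(Gp)[0]
                A = L - Q @ (Q.T @ L)
                Dp = D - Q @ (Q.T @ D)
            else:
                A, Dp = L, D
            u = _best_orientation(A, Dp)
            w = np.linalg.lstsq(
                np.column_stack([Gp, L @ u]), D, rcond=None
            )[0][-1]
            if w[np.argmax(np.abs(w))] < 0:
                u = -u
            max_change = max(max_change, 1.0 - abs(float(u @ d.orientation)))
            d.orientation = u
        if max_change < 1e-12:
            break

    report = []
    for d in seeded:
        win = win_by_label.get(d.label)
        if win is None:
            continue
        mask = _window_slice(evoked, win)
        D = _avg_ref(evoked.data[:, mask])
        G_before = _oriented_gains(model.dipoles, head, montage)
        W_b = source_waveforms(D, model.dipoles, head, montage, gains=G_before)
        rv_before = residual_variance(D, G_before @ W_b)
        G_after = _oriented_gains(seeded, head, montage)
        W_a = source_waveforms(D, seeded, head, montage, gains=G_after)
        rv_after = residual_variance(D, G_after @ W_a)
        report.append(
            {
                "window": d.label,
                "seed_roi": d.seed_roi,
                "rv_before": rv_before,
                "rv_after": rv_after,
            }
        )

    times = evoked.times_ms
    W_full = source_waveforms(evoked.data, seeded, head, montage)
    lo, hi = model.total_window_ms
    tot_mask = (times >= lo) & (times <= hi)
    G = _oriented_gains(seeded, head, montage)
    total_rv = residual_variance(
        _avg_ref(evoked.data)[:, tot_mask], (G @ W_full)[:, tot_mask]
    )
    return SourceModel(
        dipoles=seeded,
        waveforms=W_full,
        times_ms=times,
        window_report=report,
        total_rv=total_rv,
        total_window_ms=model.total_window_ms,
        meta={**model.meta, "seeded": True},
    )


# --------------------------------------------------------------------------
# residual orthogonality test
# --------------------------------------------------------------------------


def rot_test(
    residuals: np.ndarray,
    waveforms: np.ndarray,
    gains: np.ndarray,
    alpha: float = 0.05,
) -> list[dict]:
    """Residual orthogonality test per dipole.

    The residual time course projected onto each dipole's scalp pattern is
    correlated (Pearson) with that dipole's source waveform; |r| with
    two-sided p < ``alpha`` flags an orthogonality violation (the model has
    systematically misassigned variance).  Zero-variance projections are
    trivially orthogonal and pass with r = 0.
    """
    out = []
    for i in range(waveforms.shape[0]):
        g = gains[:, i]
        proj = g @ residuals / (g @ g)
        w = waveforms[i]
        if np.std(proj) == 0 or np.std(w) == 0:
            out.append({"dipole": i, "r": 0.0, "p": 1.0, "pass": True})
            continue
        r, p = stats.pearsonr(w, proj)
        out.append({"dipole": i, "r": float(r), "p": float(p), "pass": bool(p >= alpha)})
    return out
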