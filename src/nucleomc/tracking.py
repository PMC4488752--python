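"""Single-particle-tracking simulation and diffusion analyses.

Trajectories are bleaching-limited: the number of frames an emitter survives
is geometric (mean 10 frames by default), so for every 1000 trajectories
about ``1000 * 0.9^18 = 150`` exceed 18 frames.  Analyses follow the
standard single-molecule conventions: ensemble MSD(tau) as a running average
over overlapping windows; per-trajectory diffusion estimates
``D_i = msd_i(tau) / (4 tau)`` (2D, projected positions); and a
two-component decomposition of the D_i histogram in which each component's
sampling distribution is the gamma distribution implied by averaging squared
Gaussian displacements over a finite trajectory.

Units: positions nm, time s, diffusion coefficients um^2/s
(1 um^2 = 1e6 nm^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .geometry import Spherocylinder

NM2_PER_UM2 = 1.0e6


class TrackingConfigError(ValueError):
    pass


@dataclass
class Trajectory:
    """Time-stamped positions of one emitter."""

    positions_nm: np.ndarray   # (L, dim)
    dt_s: float
    emitter_id: int = 0

    @property
    def length(self) -> int:
        return len(self.positions_nm)


@dataclass
class MsdCurve:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    counts: np.ndarray   # contributing windows per lag


@dataclass
class DiffusionEstimate:
    D_um2_s: float
    n_windows: int
    length: int
    species: str = ""


@dataclass
class TwoComponentFit:
    slow_fraction: float
    fast_fraction: float
    D_slow_um2_s: float
    D_fast_um2_s: float
    log_likelihood: float
    converged: bool
    n_tracks: int
    n_restarts: int = 0


@dataclass
class FirstPassageResult:
    mean_s: float
    median_s: float
    se_mean_s: float
    n_walkers: int
    n_absorbed: int
    analytic_center_s: float | None = None


def simulate_tracks(
    D_um2_s: float,
    dt_s: float,
    n_tracks: int,
    mean_length_frames: float = 10.0,
    region=None,
    sigma_loc_nm: float = 0.0,
    seed: int | None = None,
    dim: int = 2,
    max_reject: int = 200,
) -> list[Trajectory]:
    """Brownian trajectories with geometric (photobleaching-limited) lengths.

    Steps are Gaussian with per-axis variance ``2 D dt``.  ``region`` may be
    ``None`` (free diffusion), ``("disk", radius_nm)`` for a reflecting 2D
    disk (steps leaving the disk are resampled), or a
    :class:`~nucleomc.geometry.Spherocylinder` (``dim=3``).  Localization
    noise of SD ``sigma_loc_nm`` per coordinate is added after the walk.
    """
    if D_um2_s < 0 or dt_s <= 0:
        raise TrackingConfigError("require D >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * D_um2_s * NM2_PER_UM2 * dt_s)
    p = 1.0 / mean_length_frames
    lengths = rng.geometric(p, size=n_tracks)
    tracks = []
    for tid, L in enumerate(lengths):
        pos = np.zeros((L, dim))
        pos[0] = _initial_point(region, dim, rng)
        for t in range(1, L):
            ok = False
            for _ in range(max_reject):
                cand = pos[t - 1] + rng.normal(scale=step_sd, size=dim)
                if _inside(region, cand):
                    ok = True
                    break
            pos[t] = cand if ok else pos[t - 1]
        if sigma_loc_nm > 0:
            pos = pos + rng.normal(scale=sigma_loc_nm, size=pos.shape)
        tracks.append(Trajectory(pos, dt_s, tid))
    return tracks


def _initial_point(region, dim, rng):
    if region is None:
        return np.zeros(dim)
    if isinstance(region, tuple) and region[0] == "disk":
        a = region[1]
        while True:
            p = rng.uniform(-a, a, size=2)
            if p @ p <= a * a:
                out = np.zeros(dim)
                out[:2] = p
                return out
    if isinstance(region, Spherocylinder):
        return region.sample_uniform(1, rng)[0]
    raise TrackingConfigError(f"unsupported region {region!r}")


def _inside(region, p):
    if region is None:
        return True
    if isinstance(region, tuple) and region[0] == "disk":
        q = p[:2]
        return q @ q <= region[1] ** 2
    return region.contains(p)


def msd(tracks: list[Trajectory], max_lag: int) -> MsdCurve:
    """Ensemble MSD(tau): running average over every trajectory's overlapping
    windows, then over trajectories, weighted by window counts."""
    usable = [t for t in tracks if t.length >= 2]
    if not usable:
        raise TrackingConfigError("need at least one trajectory of length >= 2")
    longest = max(t.length for t in usable)
    if max_lag >= longest:
        warnings.warn(
            f"max_lag {max_lag} >= longest trajectory ({longest}); truncating"
        )
        max_lag = longest - 1
    dt = usable[0].dt_s
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    counts[0] = sum(t.length for t in usable)
    for t in usable:
        p = t.positions_nm
        for lag in range(1, min(max_lag, t.length - 1) + 1):
            d = p[lag:] - p[:-lag]
            sums[lag] += (d * d).sum()
            counts[lag] += len(d)
    msd_vals = np.zeros(max_lag + 1)
    nz = counts[1:] > 0
    msd_vals[1:][nz] = sums[1:][nz] / counts[1:][nz] / NM2_PER_UM2
    return MsdCurve(dt * np.arange(max_lag + 1), msd_vals, counts)


def estimate_Di(track: Trajectory, lag: int = 1,
                species: str = "") -> DiffusionEstimate | None:
    """Per-trajectory diffusion estimate D_i = msd_i(tau) / (4 tau).

    msd_i is the mean squared displacement over all overlapping windows of
    ``lag`` frames within the single trajectory; tau = lag * dt; the factor
    4 is the 2D (projected) convention.  Trajectories with length <= lag are
    skipped (returns None).
    """
    if track.length <= lag:
        return None
    p = track.positions_nm[:, :2]
    d = p[lag:] - p[:-lag]
    msd_i = (d * d).sum(axis=1).mean() / NM2_PER_UM2
    tau = lag * track.dt_s
    return DiffusionEstimate(float(msd_i / (4.0 * tau)), len(d),
                             track.length, species)


def estimate_Di_ensemble(tracks: list[Trajectory], lag: int = 1):
    """D_i for every usable track; returns (estimates, n_skipped)."""
    out = []
    skipped = 0
    for t in tracks:
        e = estimate_Di(t, lag)
        if e is None:
            skipped += 1
        else:
            out.append(e)
    return out, skipped


def _mixture_loglik(D, m, f, comp):
    """Log-likelihood of gamma mixture: D_i ~ Gamma(shape=m_i, mean=comp_j)."""
    D = np.maximum(D, 1e-12)
    ll = np.empty((len(D), len(comp)))
    for j, Dj in enumerate(comp):
        rate = m / Dj
        ll[:, j] = (m * np.log(rate) + (m - 1) * np.log(D) - rate * D
                    - gammaln(m))
    ll = ll + np.log(np.maximum(f, 1e-300))
    mx = ll.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(ll - mx).sum(axis=1))
    return lse.sum(), ll, lse


def fit_two_components(
    estimates: list[DiffusionEstimate],
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> TwoComponentFit:
    """Maximum-likelihood two-component decomposition of a D_i sample.

    For free diffusion, the per-track estimate at lag 1 is a mean of
    ``m_i = L_i - 1`` independent squared Gaussian displacements, so
    ``D_i | component j ~ Gamma(shape=m_i, mean=D_j)``.  The mixture of the
    two gamma families is fit by EM with ``n_restarts`` random restarts
    (fixed sub-seeds); ties are broken by likelihood, then by lower D_slow.
    """
    if len(estimates) < 50:
        raise TrackingConfigError("need at least 50 D_i estimates")
    D = np.array([e.D_um2_s for e in estimates])
    m = np.array([e.n_windows for e in estimates], dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for r in range(n_restarts):
        qlo, qhi = sorted(rng.uniform(0.1, 0.9, size=2))
        comp = np.array([
            max(np.quantile(D, qlo), 1e-9),
            max(np.quantile(D, qhi), 2e-9),
        ])
        if comp[1] <= comp[0]:
            comp[1] = comp[0] * 2.0
        f = np.array([0.5, 0.5])
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            ll_total, ll, lse = _mixture_loglik(D, m, f, comp)
            resp = np.exp(ll - lse[:, None])
            f = resp.mean(axis=0)
            w = resp * m[:, None]
            comp = (w * D[:, None]).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-300)
            comp = np.maximum(comp, 1e-12)
            if abs(ll_total - prev) < tol * (1 + abs(ll_total)):
                converged = True
                break
            prev = ll_total
        if converged:
            n_ok += 1
        order = np.argsort(comp)
        comp = comp[order]
        f = f[order]
        cand = (ll_total, -comp[0], f, comp, converged)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    ll_total, _, f, comp, converged = best
    return TwoComponentFit(
        slow_fraction=float(f[0]),
        fast_fraction=float(f[1]),
        D_slow_um2_s=float(comp[0]),
        D_fast_um2_s=float(comp[1]),
        log_likelihood=float(ll_total),
        converged=bool(n_ok > 0),
        n_tracks=len(D),
        n_restarts=n_restarts,
    )


def aspect_ratio(track: Trajectory) -> float:
    """sqrt(lambda_max / lambda_min) of the 2D gyration tensor.

    Collinear trajectories return inf (flagged degenerate); requires
    length >= 3.
    """
    if track.length < 3:
        raise TrackingConfigError("aspect ratio requires length >= 3")
    p = track.positions_nm[:, :2]
    c = p - p.mean(axis=0)
    g = c.T @ c / len(c)
    ev = np.linalg.eigvalsh(g)
    lam_min, lam_max = float(ev[0]), float(ev[1])
    if lam_min <= 1e-12 * max(lam_max, 1.0):
        return np.inf
    return float(np.sqrt(lam_max / lam_min))


def first_passage(
    D_um2_s: float,
    start_nm: tuple,
    radius_nm: float,
    n_walkers: int = 2000,
    dt_s: float = 5e-4,
    seed: int | None = None,
    max_steps: int | None = None,
    continuity_correction: bool = True,
) -> FirstPassageResult:
    """Mean/median first-passage time to an absorbing disk boundary.

    Euler-Maruyama walkers in 2D start at ``start_nm`` (strictly inside) and
    are absorbed at their first recorded crossing of the circle of radius
    ``radius_nm``.  For a walker started at the center the mean FPT has the
    closed form ``a^2 / (4 D)``, reported in ``analytic_center_s``.

    Discrete-time sampling misses continuous-path excursions beyond the
    boundary between frames, biasing the FPT upward by O(step SD).  With
    ``continuity_correction`` the detection radius is shrunk by the Siegmund
    constant (0.5826 step SD) and absorption times are shifted by half a
    step, which removes the leading-order bias.

    Raises
    ------
    TrackingConfigError
        If the per-axis step SD exceeds 5% of the starting distance to the
        boundary (dt too large for an accurate absorption time).
    """
    if D_um2_s <= 0:
        raise TrackingConfigError("require D > 0")
    start = np.asarray(start_nm, dtype=float)[:2]
    a = float(radius_nm)
    r0 = float(np.linalg.norm(start))
    if r0 >= a:
        return FirstPassageResult(0.0, 0.0, 0.0, n_walkers, n_walkers,
                                  a * a / (4.0 * D_um2_s * NM2_PER_UM2)
                                  if r0 == 0 else None)
    gap = a - r0
    step_sd = np.sqrt(2.0 * D_um2_s * NM2_PER_UM2 * dt_s)
    if step_sd > 0.05 * gap:
        raise TrackingConfigError(
            f"step SD {step_sd:.1f} nm exceeds 5% of boundary distance "
            f"{gap:.1f} nm; reduce dt"
        )
    analytic = (a * a - r0 * r0) / (4.0 * D_um2_s * NM2_PER_UM2)
    if max_steps is None:
        max_steps = int(50 * analytic / dt_s) + 1000
    rng = np.random.default_rng(seed)
    pos = np.tile(start, (n_walkers, 1))
    alive = np.ones(n_walkers, dtype=bool)
    fpt = np.full(n_walkers, np.nan)
    a_det = a - 0.5826 * step_sd if continuity_correction else a
    t_off = 0.5 * dt_s if continuity_correction else 0.0
    a2 = a_det * a_det
    for step in range(1, max_steps + 1):
        n_alive = int(alive.sum())
        if n_alive == 0:
            break
        pos[alive] += rng.normal(scale=step_sd, size=(n_alive, 2))
        r2 = (pos[alive] ** 2).sum(axis=1)
        hit = r2 >= a2
        if np.any(hit):
            idx = np.flatnonzero(alive)[hit]
            fpt[idx] = step * dt_s - t_off
            alive[idx] = False
    absorbed = np.isfinite(fpt)
    t = fpt[absorbed]
    if len(t) == 0:
        raise TrackingConfigError("no walker was absorbed; increase max_steps")
    return FirstPassageResult(
        mean_s=float(t.mean()),
        median_s=float(np.median(t)),
        se_mean_s=float(t.std(ddof=1) / np.sqrt(len(t))),
        n_walkers=n_walkers,
        n_absorbed=int(absorbed.sum()),
        analytic_center_s=a * a / (4.0 * D_um2_s * NM2_PER_UM2) if r0 == 0 else None,
    )
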