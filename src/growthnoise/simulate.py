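"""Numerical integration of the full nonlinear stochastic dynamics.

The mass-fraction equations are a system of random ODEs driven by OU noise:
the OU sources are advanced with their *exact* Gaussian transition (no
discretization bias in the drivers), and the compositions by explicit Euler.
The simplex constraint ``sum(phi) = 1`` is dynamically invariant
(``d(sum phi)/dt = mu (1 - sum phi)``); an optional per-step projection
divides phi by its sum and records the pre-projection drift as an
integrator diagnostic.

Empirical statistics (CVs, lagged Pearson cross-correlations) follow the
same lag-sign convention as the analytics:
``r(tau) = corr(x(t + tau), y(t))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .model import (
    CellModel,
    ConfigurationError,
    DegenerateSignalError,
    InstabilityError,
    NumericsError,
)
from . import linear as _linear

__all__ = [
    "Trajectory",
    "EmpiricalXcorr",
    "simulate",
    "ou_path",
    "estimate_xcorr",
    "estimate_cv",
    "sample_stat_se",
]


@dataclass(frozen=True)
class Trajectory:
    """Recorded time series of a stochastic growth simulation.

    ``phi``/``pi`` have shape (n_records, n_species); ``noise`` has shape
    (n_records, n_sources) ordered private sources first, then shared.
    ``mu`` is recorded as ``pi.sum(axis=1)`` so the identity
    ``mu == sum_i pi_i`` holds to machine precision on the record.
    ``max_drift`` is the largest pre-projection deviation of ``sum(phi)``
    from one seen during integration.
    """

    t: np.ndarray
    phi: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    noise: np.ndarray
    ids: tuple[str, ...]
    source_ids: tuple[str, ...]
    seed: int
    dt: float
    max_drift: float

    def column(self, selector: str) -> np.ndarray:
        """Resolve a signal selector: ``"mu"``, ``"phi:<id>"`` or ``"pi:<id>"``."""
        if selector == "mu":
            return self.mu
        kind, _, pid = selector.partition(":")
        if kind not in ("phi", "pi") or pid not in self.ids:
            raise KeyError(f"unknown signal selector {selector!r}")
        j = self.ids.index(pid)
        return (self.phi if kind == "phi" else self.pi)[:, j]

    def to_frame(self):
        """Tidy long-format table: t, species, phi, pi, mu, noise (the
        species' private-source state; shared sources stay in ``noise``)."""
        import pandas as pd

        n = len(self.ids)
        nrec = self.t.size
        return pd.DataFrame(
            {
                "t": np.repeat(self.t, n),
                "species": np.tile(np.array(self.ids), nrec),
                "phi": self.phi.ravel(),
                "pi": self.pi.ravel(),
                "mu": np.repeat(self.mu, n),
                "noise": self.noise[:, :n].ravel(),
            }
        )


def ou_path(
    theta: float,
    beta: float,
    duration: float,
    dt: float,
    seed: int | np.random.Generator = 0,
    initial: float | None = None,
) -> np.ndarray:
    """Sample an OU path on a regular grid with the exact transition.

    ``N(t+dt) = N(t) exp(-beta dt) + Gaussian(0, theta^2 (1 - exp(-2 beta
    dt)) / (2 beta))``; the returned array includes the initial point, drawn
    from the stationary law unless ``initial`` is given.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    decay = math.exp(-beta * dt)
    stat_sd = theta / math.sqrt(2.0 * beta)
    step_sd = stat_sd * math.sqrt(1.0 - decay**2)
    x0 = float(rng.normal(0.0, stat_sd)) if initial is None else float(initial)
    innov = rng.normal(0.0, step_sd, size=n_steps)
    # exact AR(1) recursion, vectorized as an IIR filter
    path, _ = lfilter([1.0], [1.0, -decay], innov, zi=np.array([decay * x0]))
    return np.concatenate(([x0], path))


def simulate(
    model: CellModel,
    duration: float,
    dt: float = 1e-3,
    seed: int = 0,
    burn_in: float | None = None,
    record_every: float = 0.01,
    renormalize: bool = True,
) -> Trajectory:
    """Integrate the full stochastic dynamics of a cell model.

    Initial state: ``phi = f`` with all noise states drawn from their
    stationary laws. ``burn_in`` (default ``20 / mu0``) is integrated and
    discarded before recording starts; records are taken every
    ``record_every`` hours. Identical ``(seed, dt, duration)`` give
    bit-identical output.

    Raises :class:`InstabilityError` if any mass fraction falls below minus
    ten of its stationary standard deviation — the small-noise regime the
    model is built on no longer holds, and a smaller ``dt`` or weaker noise
    is needed.
    """
    growth = model.growth_surface()
    ids = model.ids
    f = model.f
    from .model import steady_state as _ss

    ss = _ss(model)
    all_betas = [p.private_noise.beta for p in model.proteins] + [
        s.noise.beta for s in model.shared
    ]
    if dt > 0.1 / max(max(all_betas), ss.mu0):
        raise ConfigurationError(
            "dt too coarse: require dt <= 0.1 / max(beta, mu0)"
        )
    if burn_in is None:
        burn_in = 20.0 / ss.mu0
    if duration <= burn_in:
        raise ConfigurationError("duration must exceed the burn-in")

    # floor for the instability check: 10 stationary SDs below zero.
    # Var(dphi) is GCC-independent, so this needs only the noise wiring.
    floor = -10.0 * np.sqrt(_linear.stationary_variance(_linear.linearize(model, ss)))

    n = model.n
    shared = model.shared
    n_shared = len(shared)
    m = n + n_shared
    betas = np.array(
        [p.private_noise.beta for p in model.proteins]
        + [s.noise.beta for s in shared]
    )
    thetas = np.array(
        [p.private_noise.theta for p in model.proteins]
        + [s.noise.theta for s in shared]
    )
    stat_sd = thetas / np.sqrt(2.0 * betas)
    decay = np.exp(-betas * dt)
    step_sd = stat_sd * np.sqrt(1.0 - decay**2)
    shared_idx = [
        (np.array([model.index(pid) for pid, _ in s.members]),
         np.array([wt for _, wt in s.members]))
        for s in shared
    ]
    source_ids = tuple(
        [p.private_noise.id for p in model.proteins] + [s.noise.id for s in shared]
    )

    stride = max(int(round(record_every / dt)), 1)
    n_steps = int(round(duration / dt))
    burn_steps = int(round(burn_in / dt))
    n_rec = (n_steps - burn_steps) // stride + 1

    rng = np.random.default_rng(seed)
    phi = f.copy()
    noise = rng.normal(0.0, 1.0, size=m) * stat_sd

    rec_t = np.empty(n_rec)
    rec_phi = np.empty((n_rec, n))
    rec_pi = np.empty((n_rec, n))
    rec_mu = np.empty(n_rec)
    rec_noise = np.empty((n_rec, m))

    max_drift = 0.0
    rec = 0
    chunk = 65536
    noisy = bool(np.any(thetas > 0))
    innov = None
    in_chunk = chunk  # force a draw on the first step
    for step in range(n_steps + 1):
        # synthesis rates and growth at the step start
        try:
            mud = growth.mu_d(phi, ids)
        except NumericsError as exc:
            raise InstabilityError(
                f"growth function failed at t = {step * dt:.3f} h ({exc}); "
                "reduce dt or the noise amplitudes (the small-noise regime "
                "is violated)"
            ) from exc
        contrib = noise[:n].copy()
        for s_idx, (members, weights) in enumerate(shared_idx):
            contrib[members] += weights * noise[n + s_idx]
        pi = f * mud + contrib
        mu = float(pi.sum())

        if step >= burn_steps and (step - burn_steps) % stride == 0 and rec < n_rec:
            rec_t[rec] = step * dt
            rec_phi[rec] = phi
            rec_pi[rec] = pi
            rec_mu[rec] = mu
            rec_noise[rec] = noise
            if np.any(phi < floor):
                bad = ids[int(np.argmin(phi - floor))]
                raise InstabilityError(
                    f"mass fraction of {bad!r} fell more than 10 stationary "
                    "SDs below zero; reduce dt or the noise amplitudes "
                    "(the small-noise regime is violated)"
                )
            rec += 1
        if step == n_steps:
            break

        # advance: Euler for phi, exact transition for the OU sources
        phi = phi + dt * (pi - mu * phi)
        total = phi.sum()
        if not np.isfinite(total) or total <= 0:
            raise InstabilityError(
                "composition sum became non-positive; reduce dt or the noise "
                "amplitudes (the small-noise regime is violated)"
            )
        drift = abs(total - 1.0)
        if drift > max_drift:
            max_drift = drift
        if renormalize:
            phi = phi / total
        if noisy:
            if in_chunk == chunk:
                innov = rng.standard_normal((chunk, m))
                in_chunk = 0
            noise = noise * decay + step_sd * innov[in_chunk]
            in_chunk += 1

    return Trajectory(
        t=rec_t[:rec],
        phi=rec_phi[:rec],
        pi=rec_pi[:rec],
        mu=rec_mu[:rec],
        noise=rec_noise[:rec],
        ids=ids,
        source_ids=source_ids,
        seed=seed,
        dt=dt,
        max_drift=max_drift,
    )


# ---------------------------------------------------------------------------
# empirical statistics


@dataclass(frozen=True)
class EmpiricalXcorr:
    """Estimated lagged Pearson correlation with bootstrap standard errors."""

    tau: np.ndarray
    r: np.ndarray
    se: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"tau": self.tau, "r": self.r, "se": self.se})


def _lagged_corr(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """corr(x(t+lag), y(t)) on a regular grid; lag in samples."""
    if lag >= 0:
        a, b = x[lag:], y[: y.size - lag] if lag else y
    else:
        a, b = x[: x.size + lag], y[-lag:]
    if a.size < 3:
        raise ConfigurationError("lag too large for the record")
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        raise DegenerateSignalError("correlation undefined on a constant signal")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def estimate_xcorr(
    traj: Trajectory,
    x: str,
    y: str,
    max_lag: float = 3.0,
    n_lags: int = 121,
    n_boot: int = 200,
    block: float | None = None,
    seed: int = 0,
) -> EmpiricalXcorr:
    """Lagged Pearson cross-correlation ``r(tau) = corr(x(t+tau), y(t))``.

    The lag grid has ``n_lags`` points on ``[-max_lag, max_lag]``, snapped
    to the recording stride. Standard errors come from a seeded block
    bootstrap (block length ``10 / mu0`` by default, ``n_boot`` resamples):
    lagged products are accumulated within blocks, and blocks are resampled
    with replacement, which respects the serial dependence of the record.
    """
    xs = traj.column(x)
    ys = traj.column(y)
    dt_rec = float(traj.t[1] - traj.t[0])
    if max_lag >= (traj.t[-1] - traj.t[0]) / 10.0:
        raise ConfigurationError("max_lag must be below a tenth of the record length")
    if xs.std() == 0.0 or ys.std() == 0.0:
        raise DegenerateSignalError("correlation undefined on a constant signal")

    lags_f = np.linspace(-max_lag, max_lag, n_lags) / dt_rec
    lags = np.unique(np.round(lags_f).astype(int))
    tau = lags * dt_rec
    r = np.array([_lagged_corr(xs, ys, int(l)) for l in lags])

    if block is None:
        mu0 = float(np.mean(traj.mu))
        block = 10.0 / mu0 if mu0 > 0 else 10.0
    bl = max(int(round(block / dt_rec)), 2 * int(np.max(np.abs(lags))) + 2)
    nb = xs.size // bl
    if nb < 8:
        raise ConfigurationError("record too short for the requested block length")
    xs_b = xs[: nb * bl].reshape(nb, bl)
    ys_b = ys[: nb * bl].reshape(nb, bl)

    # per-block sufficient statistics for each lag
    sum_x = xs_b.sum(axis=1)
    sum_y = ys_b.sum(axis=1)
    sum_xx = (xs_b**2).sum(axis=1)
    sum_yy = (ys_b**2).sum(axis=1)
    n_pairs = np.empty(lags.size)
    sum_xy = np.empty((lags.size, nb))
    for li, lag in enumerate(lags):
        a = int(abs(lag))
        if lag >= 0:
            prod = xs_b[:, a:] * ys_b[:, : bl - a] if a else xs_b * ys_b
        else:
            prod = xs_b[:, : bl - a] * ys_b[:, a:]
        sum_xy[li] = prod.sum(axis=1)
        n_pairs[li] = bl - a

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, nb, size=(n_boot, nb))
    boot_r = np.empty((n_boot, lags.size))
    n_tot = nb * bl
    for b in range(n_boot):
        idx = picks[b]
        mx = sum_x[idx].sum() / n_tot
        my = sum_y[idx].sum() / n_tot
        vx = sum_xx[idx].sum() / n_tot - mx**2
        vy = sum_yy[idx].sum() / n_tot - my**2
        if vx <= 0 or vy <= 0:
            boot_r[b] = np.nan
            continue
        cov = sum_xy[:, idx].sum(axis=1) / (n_pairs * nb) - mx * my
        boot_r[b] = cov / math.sqrt(vx * vy)
    se = np.nanstd(boot_r, axis=0, ddof=1)
    return EmpiricalXcorr(tau=tau, r=r, se=se)


def estimate_cv(traj: Trajectory, protein_id: str) -> float:
    """Sample CV (SD over mean) of one mass fraction on the record."""
    x = traj.column(f"phi:{protein_id}")
    m = float(x.mean())
    if m <= 0:
        raise ConfigurationError(f"mean mass fraction of {protein_id!r} is <= 0")
    return float(x.std() / m)


def sample_stat_se(
    values: np.ndarray,
    stat,
    block: int,
) -> tuple[float, float]:
    """Batch-means estimate and standard error of a statistic of a series.

    Splits the series (or paired columns) into contiguous blocks of
    ``block`` samples, applies ``stat`` to each block, and returns
    ``(stat(full series), sd(block stats) / sqrt(n_blocks))``. A simple,
    honest error bar for slowly mixing records.
    """
    values = np.asarray(values)
    nb = values.shape[0] // block
    if nb < 4:
        raise ConfigurationError("record too short for batch-means error bars")
    stats = np.array(
        [stat(values[i * block : (i + 1) * block]) for i in range(nb)], dtype=float
    )
    return float(stat(values[: nb * block])), float(stats.std(ddof=1) / math.sqrt(nb))
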