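"""Closed-form statistics of the linearized model.

Linearizing the dynamics around the mean composition ``phi0`` (with
``f = phi0``) gives a *reduced* stochastic system in which the allocation
feedback ``f_i * dmu_d`` exactly cancels the mean-field dilution term
``phi0_i * dmu_d``, so the concentration deviations are independent of the
growth-control coefficients::

    d(dphi_i)/dt = -mu0 * dphi_i + sum_s (w_si - phi0_i) * N_s
    dmu          = mu0 * sum_j C_j * dphi_j / phi0_j + sum_s N_s
    dpi_i        = phi0_i * mu0 * sum_j C_j * dphi_j / phi0_j + sum_s w_si * N_s

where ``w_si`` is source ``s``'s wiring coefficient into synthesis rate
``pi_i`` (1 for a private source, the member weight for a shared/operon
source), and ``C_j`` are the GCCs.

Every source therefore reaches the observables through two channels: the
raw OU signal ``N_s`` and its one-pole filtrate
``F_s(t) = int_0^inf exp(-mu0 r) N_s(t - r) dr``. All stationary second
moments are finite sums of exponentials in the lag, built from three
correlator kernels (the B/A/S shapes):

* ``<N(t) N(t+tau)>``                    — pure ``exp(-beta |tau|)`` (B);
* ``<F(t) N(t+tau)>``                    — asymmetric (A);
* ``<F(t) F(t+tau)>``                    — symmetric mixture of
  ``exp(-mu0 |tau|)`` and ``exp(-beta |tau|)`` (S).

Lag-sign convention used throughout the package:
``r(tau) = corr(x(t + tau), mu(t))`` — positive lag means the expression
signal is taken *later* than the growth rate. Under this convention the
concentration autogenic mode peaks at positive lag (synthesis noise enters
growth instantly and the concentration follows with a delay) and the
production control mode peaks at negative lag (production must first
accumulate into concentration before it affects growth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    CellModel,
    ConfigurationError,
    DegenerateSignalError,
    GrowthNoiseError,
    InfeasibleNoiseError,
    OUNoiseSpec,
    SteadyState,
    gcc_numeric,
    steady_state,
)

__all__ = [
    "LinearNoiseModel",
    "CrossCorrelation",
    "linearize",
    "stationary_variance",
    "stationary_cv",
    "growth_variance",
    "production_variance",
    "dual_reporter_covariance",
    "basis_functions",
    "xcorr_analytic",
    "noise_amplitudes_from_cvs",
    "peak_height",
    "asymmetry_index",
    "relative_asymmetry",
]

# relative tolerance below which beta and mu0 are treated as a repeated root
_CONFLUENT_RTOL = 1e-9


# ---------------------------------------------------------------------------
# correlator kernels


def _cov_nn(tau: np.ndarray, variance: float, beta: float) -> np.ndarray:
    """<N(t) N(t+tau)> for an OU source (B-type kernel)."""
    return variance * np.exp(-beta * np.abs(tau))


def _cov_fn(tau: np.ndarray, variance: float, beta: float, mu0: float) -> np.ndarray:
    """<F(t) N(t+tau)> where F is the one-pole (rate mu0) filtrate of N.

    A-type kernel: a pure ``exp(-beta tau)`` tail for tau >= 0 (the source
    decorrelates from the filtrate it has already driven) and a mixed
    exponential for tau < 0 (the source *leads* the filtrate, so the peak
    sits at negative tau).
    """
    tau = np.asarray(tau, dtype=float)
    out = np.empty_like(tau)
    pos = tau >= 0
    out[pos] = variance * np.exp(-beta * tau[pos]) / (mu0 + beta)
    tn = tau[~pos]
    if tn.size:
        if abs(mu0 - beta) <= _CONFLUENT_RTOL * (mu0 + beta):
            out[~pos] = variance * np.exp(mu0 * tn) * (-tn + 1.0 / (mu0 + beta))
        else:
            out[~pos] = variance * (
                (np.exp(beta * tn) - np.exp(mu0 * tn)) / (mu0 - beta)
                + np.exp(mu0 * tn) / (mu0 + beta)
            )
    return out


def _cov_ff(tau: np.ndarray, variance: float, beta: float, mu0: float) -> np.ndarray:
    """<F(t) F(t+tau)>: symmetric S-type kernel; value at 0 is
    ``Var(N) / (mu0 (mu0 + beta))``."""
    t = np.abs(np.asarray(tau, dtype=float))
    if abs(mu0 - beta) <= _CONFLUENT_RTOL * (mu0 + beta):
        return variance * np.exp(-mu0 * t) * (1.0 / (mu0 * (mu0 + beta)) + t / (mu0 + beta))
    return variance * (
        np.exp(-mu0 * t) / (mu0 * (mu0 + beta))
        + (np.exp(-beta * t) - np.exp(-mu0 * t)) / ((mu0 + beta) * (mu0 - beta))
    )


def basis_functions(
    source: OUNoiseSpec, mu0: float, tau: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three correlator shapes (S, A, B) of one source, unit-normalized.

    ``B`` is the source autocovariance shape ``exp(-beta |tau|)``; ``A`` the
    source–filtrate cross-covariance shape; ``S`` the filtrate
    autocovariance shape. Each is scaled to 1 at ``tau = 0``. ``S`` and
    ``B`` are even in tau; all asymmetry of the cross-correlations comes
    from ``A``-type terms. The confluent case ``beta = mu0`` uses the
    repeated-root closed form.
    """
    if mu0 <= 0:
        raise ConfigurationError("basis_functions: mu0 must be > 0")
    tau = np.asarray(tau, dtype=float)
    v = 1.0  # shapes are variance-independent after normalization
    s = _cov_ff(tau, v, source.beta, mu0)
    s /= _cov_ff(np.zeros(1), v, source.beta, mu0)[0]
    a = _cov_fn(tau, v, source.beta, mu0)
    a /= _cov_fn(np.zeros(1), v, source.beta, mu0)[0]
    b = _cov_nn(tau, v, source.beta)
    return s, a, b


# ---------------------------------------------------------------------------
# the linearized model


@dataclass(frozen=True)
class LinearNoiseModel:
    """The model linearized around its steady state.

    Arrays: ``phi0`` and ``gcc`` have one entry per protein; ``betas`` and
    ``variances`` one entry per noise source; ``wiring`` has shape
    ``(n_sources, n_proteins)`` with rows summing to one. ``source_kind``
    tags each source ``("private", protein_id)`` or ``("shared", group_id)``.
    """

    ids: tuple[str, ...]
    phi0: np.ndarray
    mu0: float
    gcc: np.ndarray
    source_ids: tuple[str, ...]
    source_kind: tuple[tuple[str, str], ...]
    betas: np.ndarray
    variances: np.ndarray
    wiring: np.ndarray

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ConfigurationError("LinearNoiseModel: mu0 must be > 0")
        if self.wiring.shape != (len(self.source_ids), len(self.ids)):
            raise ConfigurationError("LinearNoiseModel: wiring shape mismatch")
        rows = self.wiring.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ConfigurationError("LinearNoiseModel: wiring rows must sum to 1")

    # -- derived arrays ----------------------------------------------------
    @property
    def drive(self) -> np.ndarray:
        """Coefficient of each source in each d(dphi_i): ``w_si - phi0_i``."""
        return self.wiring - self.phi0[None, :]

    @property
    def v(self) -> np.ndarray:
        """Per-source filtrate variance ``Var(N_s) / (mu0 (mu0 + beta_s))``."""
        return self.variances / (self.mu0 * (self.mu0 + self.betas))

    @property
    def k(self) -> np.ndarray:
        """GCC channel gain of each source: coefficient of ``F_s`` in dmu."""
        return self.mu0 * (self.drive @ (self.gcc / self.phi0))

    def index(self, protein_id: str) -> int:
        try:
            return self.ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def private_source_index(self, protein_id: str) -> int | None:
        for s, (kind, owner) in enumerate(self.source_kind):
            if kind == "private" and owner == protein_id:
                return s
        return None


def linearize(model: CellModel, ss: SteadyState | None = None) -> LinearNoiseModel:
    """Build the linearized system for a cell model.

    Wiring: each private source drives only its own protein with weight 1;
    each shared source drives its members with the declared weights. GCCs
    are taken from the model when fully specified, otherwise differentiated
    from the growth function.
    """
    if ss is None:
        ss = steady_state(model)
    gcc = model.gcc_vector()
    if gcc is None:
        if model.growth is None:
            raise ConfigurationError(
                "model lacks per-protein GCCs and has no growth function to "
                "differentiate"
            )
        gcc = gcc_numeric(model.growth, ss.phi0, model.ids)
    n = model.n
    source_ids: list[str] = []
    source_kind: list[tuple[str, str]] = []
    betas: list[float] = []
    variances: list[float] = []
    rows: list[np.ndarray] = []
    for i, p in enumerate(model.proteins):
        w = np.zeros(n)
        w[i] = 1.0
        source_ids.append(p.private_noise.id)
        source_kind.append(("private", p.id))
        betas.append(p.private_noise.beta)
        variances.append(p.private_noise.variance)
        rows.append(w)
    for s in model.shared:
        w = np.zeros(n)
        for pid, weight in s.members:
            w[model.index(pid)] += weight
        source_ids.append(s.noise.id)
        source_kind.append(("shared", s.id))
        betas.append(s.noise.beta)
        variances.append(s.noise.variance)
        rows.append(w)
    return LinearNoiseModel(
        ids=model.ids,
        phi0=ss.phi0,
        mu0=ss.mu0,
        gcc=np.asarray(gcc, dtype=float),
        source_ids=tuple(source_ids),
        source_kind=tuple(source_kind),
        betas=np.array(betas),
        variances=np.array(variances),
        wiring=np.vstack(rows),
    )


# ---------------------------------------------------------------------------
# stationary moments


def stationary_variance(lnm: LinearNoiseModel) -> np.ndarray:
    """Stationary Var(dphi_i) for every protein.

    ``Var(dphi_i) = sum_s (w_si - phi0_i)^2 Var(N_s) / (mu0 (mu0+beta_s))``.
    Independent of the GCC vector (the allocation feedback cancels the
    dilution of the mean exactly at linear order).
    """
    return (lnm.drive**2 * lnm.v[:, None]).sum(axis=0)


def stationary_cv(lnm: LinearNoiseModel) -> np.ndarray:
    """Stationary coefficient of variation of each mass fraction."""
    if np.any(lnm.phi0 <= 0):
        bad = [i for i, p in zip(lnm.ids, lnm.phi0) if p <= 0]
        raise ConfigurationError(f"CV undefined for zero-mean proteins: {bad}")
    return np.sqrt(stationary_variance(lnm)) / lnm.phi0


def growth_variance(lnm: LinearNoiseModel) -> float:
    """Stationary Var(dmu): each source contributes through its raw channel,
    its filtrate channel (gain k_s) and their cross term."""
    k = lnm.k
    return float(
        np.sum(
            k**2 * lnm.v
            + 2.0 * k * lnm.variances / (lnm.mu0 + lnm.betas)
            + lnm.variances
        )
    )


def production_variance(lnm: LinearNoiseModel, protein_id: str) -> float:
    """Stationary Var(dpi_i) for one protein."""
    i = lnm.index(protein_id)
    k = lnm.k
    w = lnm.wiring[:, i]
    p = lnm.phi0[i]
    return float(
        np.sum(
            (p * k) ** 2 * lnm.v
            + 2.0 * p * k * w * lnm.variances / (lnm.mu0 + lnm.betas)
            + w**2 * lnm.variances
        )
    )


def dual_reporter_covariance(
    phi0_b: float,
    noise_b: OUNoiseSpec,
    background_sources: Sequence[OUNoiseSpec],
    mu0: float,
) -> tuple[float, float, float]:
    """Normalized covariance between two identical reporter constructs.

    For reporters R and G with identical mean fraction ``phi0_b`` and
    identical private sources (``noise_b`` each), the stationary covariance
    normalized by ``phi0_b**2`` splits into::

        transmission = -2 (1 - phi0_b) / phi0_b * Var(N_b) / (mu0 (mu0+beta_b))
        other        = sum_j Var(N_j) / (mu0 (mu0+beta_j))   over background j

    The transmission term is strictly negative whenever the reporters are
    noisy: synthesis of one reporter dilutes the other. The conventional
    reading of reporter covariance as "extrinsic noise" misses this term.

    Returns ``(total, transmission, other)``.
    """
    if phi0_b <= 0 or phi0_b >= 0.5:
        raise ConfigurationError("dual reporters need 0 < phi0_b < 0.5")
    vb = noise_b.variance / (mu0 * (mu0 + noise_b.beta))
    transmission = -2.0 * (1.0 - phi0_b) / phi0_b * vb
    other = float(
        sum(s.variance / (mu0 * (mu0 + s.beta)) for s in background_sources)
    )
    return transmission + other, transmission, other


# ---------------------------------------------------------------------------
# analytic cross-correlations and the noise-mode decomposition


@dataclass(frozen=True)
class CrossCorrelation:
    """A cross-correlation curve with its additive noise-mode decomposition.

    ``total(tau) == sum(modes.values())(tau)`` to machine precision. The
    canonical modes are ``control``, ``autogenic`` and, depending on the
    signal, ``dilution`` (concentration) or ``transmission`` (production);
    absent modes are all-zero arrays. ``splits`` further separates the
    operon-level and private-reporter instances of the control and autogenic
    modes for operon members. ``basis`` holds the unit-normalized S/A/B
    shapes of the focal protein's private source, for plotting.
    """

    protein_id: str
    signal: str
    tau: np.ndarray
    total: np.ndarray
    modes: dict[str, np.ndarray]
    splits: dict[str, np.ndarray]
    basis: dict[str, np.ndarray]
    sigma_x: float
    sigma_mu: float
    normalized: bool

    def to_frame(self):
        """Tidy table: tau, total, and the mode columns (absent modes 0)."""
        import pandas as pd

        cols = {
            "tau": self.tau,
            "total": self.total,
            "control": self.modes["control"],
            "control_private": self.splits["control_private"],
            "autogenic": self.modes["autogenic"],
            "autogenic_private": self.splits["autogenic_private"],
            "dilution": self.modes["dilution"],
            "transmission": self.modes["transmission"],
        }
        return pd.DataFrame(cols)


def xcorr_analytic(
    lnm: LinearNoiseModel,
    protein_id: str,
    signal: str = "concentration",
    tau: np.ndarray | None = None,
    normalize: bool = True,
) -> CrossCorrelation:
    """Exact stationary cross-correlation of an expression signal with growth.

    ``signal`` selects the focal observable: ``"concentration"`` (the mass
    fraction ``phi_i``) or ``"production"`` (the synthesis rate ``pi_i``).
    The curve is ``r(tau) = corr(x(t + tau), mu(t))`` — positive lag means
    the expression signal trails the growth rate.

    The curve is decomposed additively into named noise modes:

    concentration
        * control: the focal protein's sources transferred to growth through
          the GCC channel (S-type, symmetric);
        * autogenic: the same sources entering growth instantly because
          ``mu = sum pi`` (A-type, peak at positive lag);
        * dilution: every source's growth fluctuations diluting the focal
          concentration, ``-phi0_i`` times the growth channel (mixed).
    production
        * control: focal sources reaching growth after accumulating into
          concentration (A-type, peak at negative lag);
        * autogenic: focal sources correlating with their own instantaneous
          entry in ``mu`` (B-type, symmetric);
        * transmission: every source feeding back into ``pi_i`` through
          ``mu_d`` (GCC-gain weighted, mixed).

    For an operon member the control and autogenic modes each have a
    private-reporter and an operon-level instance (see ``splits``).

    With ``normalize=True`` the curve is Pearson-normalized (divide by
    ``sigma_x sigma_mu``); modes are scaled identically so the decomposition
    stays additive.
    """
    if tau is None:
        tau = np.linspace(-3.0, 3.0, 121)
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        raise ConfigurationError("xcorr_analytic: empty tau grid")
    if signal not in ("concentration", "production"):
        raise ConfigurationError(f"unknown signal {signal!r}")
    i = lnm.index(protein_id)
    m = len(lnm.source_ids)
    k = lnm.k
    w = lnm.wiring[:, i]
    p = lnm.phi0[i]

    # Per-source kernel evaluations. r(tau) = <x(t+tau) mu(t)> is the
    # t-forward covariance evaluated at -tau, so A-type kernels appear with
    # both orientations below.
    cff = np.empty((m, tau.size))
    cfn_fwd = np.empty((m, tau.size))  # <F(t) N(t+tau)>
    cfn_rev = np.empty((m, tau.size))  # <N(t) F(t+tau)> = cfn(-tau)
    cnn = np.empty((m, tau.size))
    for s in range(m):
        cff[s] = _cov_ff(tau, lnm.variances[s], lnm.betas[s], lnm.mu0)
        cfn_fwd[s] = _cov_fn(tau, lnm.variances[s], lnm.betas[s], lnm.mu0)
        cfn_rev[s] = _cov_fn(-tau, lnm.variances[s], lnm.betas[s], lnm.mu0)
        cnn[s] = _cov_nn(tau, lnm.variances[s], lnm.betas[s])

    # growth channel of each source, as seen from an x(t+tau) observer
    growth_channel = k[:, None] * cff + cfn_rev

    private = lnm.private_source_index(protein_id)
    shared_members = [
        s
        for s in range(m)
        if lnm.source_kind[s][0] == "shared" and w[s] > 0.0
    ]

    zeros = np.zeros_like(tau)
    splits = {
        "control_private": zeros.copy(),
        "control_operon": zeros.copy(),
        "autogenic_private": zeros.copy(),
        "autogenic_operon": zeros.copy(),
    }

    if signal == "concentration":
        if private is not None:
            splits["control_private"] = w[private] * k[private] * cff[private]
            splits["autogenic_private"] = w[private] * cfn_rev[private]
        for s in shared_members:
            splits["control_operon"] += w[s] * k[s] * cff[s]
            splits["autogenic_operon"] += w[s] * cfn_rev[s]
        dilution = -p * growth_channel.sum(axis=0)
        transmission = zeros.copy()
        sigma_x = math.sqrt(stationary_variance(lnm)[i])
    else:
        if private is not None:
            splits["control_private"] = w[private] * k[private] * cfn_fwd[private]
            splits["autogenic_private"] = w[private] * cnn[private]
        for s in shared_members:
            splits["control_operon"] += w[s] * k[s] * cfn_fwd[s]
            splits["autogenic_operon"] += w[s] * cnn[s]
        dilution = zeros.copy()
        transmission = p * (k[:, None] * growth_channel).sum(axis=0)
        sigma_x = math.sqrt(production_variance(lnm, protein_id))

    control = splits["control_private"] + splits["control_operon"]
    autogenic = splits["autogenic_private"] + splits["autogenic_operon"]
    total = control + autogenic + dilution + transmission
    sigma_mu = math.sqrt(growth_variance(lnm))

    if normalize:
        if sigma_x == 0.0 or sigma_mu == 0.0:
            raise DegenerateSignalError(
                "Pearson normalization undefined: a signal has zero variance"
            )
        scale = 1.0 / (sigma_x * sigma_mu)
        total = total * scale
        control = control * scale
        autogenic = autogenic * scale
        dilution = dilution * scale
        transmission = transmission * scale
        splits = {name: arr * scale for name, arr in splits.items()}

    basis: dict[str, np.ndarray] = {}
    if private is not None:
        spec = OUNoiseSpec(
            lnm.source_ids[private], 1.0, lnm.betas[private]
        )
        s_b, a_b, b_b = basis_functions(spec, lnm.mu0, tau)
        basis = {"S": s_b, "A": a_b, "B": b_b}

    return CrossCorrelation(
        protein_id=protein_id,
        signal=signal,
        tau=tau,
        total=total,
        modes={
            "control": control,
            "autogenic": autogenic,
            "dilution": dilution,
            "transmission": transmission,
        },
        splits=splits,
        basis=basis,
        sigma_x=sigma_x,
        sigma_mu=sigma_mu,
        normalized=normalize,
    )


def peak_height(xc: CrossCorrelation) -> float:
    """Maximum of the total curve over the lag grid."""
    return float(np.max(xc.total))


def asymmetry_index(xc: CrossCorrelation) -> float:
    """Signed skew of the curve: ``int_0^T [r(tau) - r(-tau)] dtau``.

    Requires a lag grid symmetric about zero. Positive values mean more
    weight at positive lag (expression trailing growth).
    """
    tau = xc.tau
    if not np.allclose(tau, -tau[::-1]):
        raise ConfigurationError("asymmetry_index needs a symmetric tau grid")
    diff = xc.total - xc.total[::-1]
    pos = tau >= 0
    return float(np.trapezoid(diff[pos], tau[pos]))


def relative_asymmetry(xc: CrossCorrelation) -> float:
    """Scale-free shape asymmetry: :func:`asymmetry_index` divided by the
    peak height. Invariant to the curve's amplitude, so it tracks how
    skewed the *shape* is as conditions change."""
    return asymmetry_index(xc) / peak_height(xc)


# ---------------------------------------------------------------------------
# noise-amplitude fitting (inverse of the CV formula)


def noise_amplitudes_from_cvs(
    phi0: np.ndarray,
    mu0: float,
    betas: np.ndarray,
    wiring: np.ndarray,
    target_cv: np.ndarray,
    amplitude_ties: Sequence[tuple[int, int, float]] = (),
    protein_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Solve for source amplitudes theta that reproduce target CVs exactly.

    Inverts the stationary-CV relation: writing
    ``v_s = Var(N_s) / (mu0 (mu0 + beta_s))``, the targets satisfy the
    linear system ``target_cv_i^2 * phi0_i^2 = sum_s (w_si - phi0_i)^2 v_s``.
    ``amplitude_ties`` lists ``(dependent, base, ratio)`` source indices with
    ``theta_dep = ratio * theta_base``; each tie eliminates one unknown.

    Singular or non-square systems are solved in the least-squares sense
    (minimum-norm among exact solutions) and the forward residual is
    checked: a two-protein cell, for instance, has rank one — both CV
    equations carry the same information because the mass fractions sum to
    one — so only the constrained (tied-amplitude) inversion pins down the
    individual sources.

    Returns the full theta vector (dependent sources included). Raises
    :class:`InfeasibleNoiseError` naming the proteins whose equations force
    a negative source variance, and :class:`ConfigurationError` when the
    targets are mutually inconsistent.
    """
    phi0 = np.asarray(phi0, dtype=float)
    betas = np.asarray(betas, dtype=float)
    wiring = np.asarray(wiring, dtype=float)
    target_cv = np.asarray(target_cv, dtype=float)
    n_prot = phi0.size
    n_src = betas.size
    if wiring.shape != (n_src, n_prot):
        raise ConfigurationError("noise_amplitudes_from_cvs: wiring shape mismatch")
    if np.any(target_cv <= 0):
        raise ConfigurationError("target CVs must be positive")

    drive2 = (wiring - phi0[None, :]) ** 2  # (m, n)
    coeff = drive2.T.copy()  # (n, m): equations x sources, in v-space
    rhs = (target_cv * phi0) ** 2

    # fold tied sources into their base columns
    dep_to_base: dict[int, tuple[int, float]] = {}
    for dep, base, ratio in amplitude_ties:
        if dep == base:
            raise ConfigurationError("amplitude tie references a source to itself")
        # v ratio implied by a theta ratio (beta factors generally differ)
        v_ratio = ratio**2 * (betas[base] * (mu0 + betas[base])) / (
            betas[dep] * (mu0 + betas[dep])
        )
        coeff[:, base] += v_ratio * coeff[:, dep]
        dep_to_base[dep] = (base, v_ratio)
    free = [s for s in range(n_src) if s not in dep_to_base]
    a = coeff[:, free]
    v_free = None
    if a.shape[0] == a.shape[1]:
        try:
            v_free = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            v_free = None
        if v_free is not None and not np.all(np.isfinite(v_free)):
            v_free = None
    if v_free is None:
        v_free, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    resid = float(np.linalg.norm(a @ v_free - rhs))
    if resid > 1e-9 * max(float(np.linalg.norm(rhs)), 1e-30):
        raise ConfigurationError(
            "CV targets are mutually inconsistent (no amplitude vector "
            f"reproduces them; residual {resid:.3e})"
        )
    v = np.empty(n_src)
    v[free] = v_free
    for dep, (base, v_ratio) in dep_to_base.items():
        v[dep] = v_ratio * v[base]

    scale = float(np.max(np.abs(v))) or 1.0
    if np.any(v < -1e-12 * scale):
        # name the proteins whose own (dominant) source went negative
        bad_sources = np.flatnonzero(v < -1e-12 * scale)
        owners = sorted({int(np.argmax(drive2[s])) for s in bad_sources})
        names = (
            [protein_ids[i] for i in owners]
            if protein_ids is not None
            else [f"protein#{i}" for i in owners]
        )
        raise InfeasibleNoiseError(names)
    v = np.maximum(v, 0.0)
    variances = v * mu0 * (mu0 + betas)
    return np.sqrt(2.0 * betas * variances)
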