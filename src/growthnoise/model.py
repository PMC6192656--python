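"""Core objects of the integrated expression–metabolism–growth model.

A cell is described by the proteome mass fractions ``phi_i`` of its protein
species, which sum to one. Growth dilutes every species at the instantaneous
growth rate ``mu``, while synthesis replenishes them::

    dphi_i/dt = pi_i - mu * phi_i

The synthesis rate (per unit protein mass) of species ``i`` is a fixed share
``f_i`` of the deterministic, composition-dependent growth rate, perturbed by
zero-mean Ornstein–Uhlenbeck (OU) noise::

    pi_i = f_i * mu_d(phi) + <wired noise sources>

and, because the mass fractions sum to one, the growth rate equals the total
synthesis rate::

    mu = sum_i pi_i = mu_d(phi) + sum_s N_s

``mu_d`` is *intensive*: scaling all abundances by a common factor leaves the
growth rate unchanged. Its logarithmic sensitivities at the mean composition
are growth-control coefficients (GCCs), which sum to zero; the corresponding
flux-control coefficients (FCCs) of the extensive biomass flux satisfy
``C_i^J = C_i^mu + phi_i`` and sum to one.

This module defines the model containers, the steady state, growth-control
analysis, and the two-protein toy model used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GrowthNoiseError",
    "ConfigurationError",
    "NumericsError",
    "InfeasibleNoiseError",
    "InstabilityError",
    "DegenerateSignalError",
    "OUNoiseSpec",
    "ProteinSpec",
    "SharedNoiseSpec",
    "GrowthFunction",
    "MonodGrowth",
    "LogLinearGrowth",
    "LinearizedGrowth",
    "CellModel",
    "SteadyState",
    "ControlAnalysis",
    "steady_state",
    "gcc_numeric",
    "monod_log_slope",
    "gcc_fcc_convert",
    "nonmetabolic_sector",
    "make_two_protein_toy",
    "round_sig",
]


class GrowthNoiseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GrowthNoiseError):
    """An invalid or incomplete model specification."""


class NumericsError(GrowthNoiseError):
    """A numerical operation produced non-finite or unusable values."""


class InfeasibleNoiseError(GrowthNoiseError):
    """Target CVs cannot be met with nonnegative source variances.

    Carries the ids of proteins whose target CV lies below the extrinsic
    floor imposed by the other sources.
    """

    def __init__(self, protein_ids: Sequence[str]):
        self.protein_ids = list(protein_ids)
        super().__init__(
            "target CVs infeasible (below the extrinsic floor) for proteins: "
            + ", ".join(self.protein_ids)
        )


class InstabilityError(GrowthNoiseError):
    """The integrator left the small-noise regime."""


class DegenerateSignalError(GrowthNoiseError):
    """A statistic was requested on a constant (zero-variance) signal."""


# ---------------------------------------------------------------------------
# noise sources


@dataclass(frozen=True)
class OUNoiseSpec:
    """One zero-mean Ornstein–Uhlenbeck noise source.

    The source obeys ``dN = -beta * N dt + theta dW`` with amplitude
    ``theta`` (units h^-3/2) and reversion rate ``beta`` (h^-1); its
    stationary variance is ``theta**2 / (2 * beta)`` (h^-2) and its
    autocorrelation time is ``1 / beta``.
    """

    id: str
    theta: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.theta >= 0.0):
            raise ConfigurationError(f"noise source {self.id!r}: theta must be >= 0")
        if not (self.beta > 0.0):
            raise ConfigurationError(f"noise source {self.id!r}: beta must be > 0")

    @property
    def variance(self) -> float:
        """Stationary variance theta^2 / (2 beta), in h^-2."""
        return self.theta**2 / (2.0 * self.beta)


@dataclass(frozen=True)
class ProteinSpec:
    """One protein species.

    Parameters
    ----------
    id : str
        Species label.
    f : float
        Allocation fraction: the share of the metabolic flux directed to
        this species' synthesis. At stationarity the mean mass fraction
        equals ``f``.
    private_noise : OUNoiseSpec
        The species' own synthesis-noise source.
    gcc : float, optional
        Growth-control coefficient. May be omitted when the model carries a
        growth function from which GCCs can be differentiated.
    nonmetabolic : bool
        If set, the species carries no flux control; its GCC is ``-f``.
    operon : str, optional
        Label of a shared-noise group this species belongs to.
    """

    id: str
    f: float
    private_noise: OUNoiseSpec
    gcc: float | None = None
    nonmetabolic: bool = False
    operon: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ConfigurationError(f"protein {self.id!r}: f must lie in [0, 1]")
        if self.nonmetabolic and self.gcc is not None:
            if abs(self.gcc + self.f) > 1e-9:
                raise ConfigurationError(
                    f"protein {self.id!r}: non-metabolic species must have "
                    f"gcc = -f = {-self.f:.6g}, got {self.gcc:.6g}"
                )


@dataclass(frozen=True)
class SharedNoiseSpec:
    """A noise source shared by several proteins (e.g. one operon).

    ``members`` lists ``(protein_id, weight)`` pairs; the weights are
    nonnegative and sum to one so that the group's source enters the summed
    synthesis rate — and hence the growth rate — exactly once.
    """

    id: str
    noise: OUNoiseSpec
    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple((str(p), float(w)) for p, w in self.members))
        if not self.members:
            raise ConfigurationError(f"shared source {self.id!r}: no members")
        weights = [w for _, w in self.members]
        if any(w < 0 for w in weights):
            raise ConfigurationError(f"shared source {self.id!r}: negative member weight")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"shared source {self.id!r}: member weights must sum to 1, "
                f"got {sum(weights):.12g}"
            )


# ---------------------------------------------------------------------------
# growth functions


class GrowthFunction:
    """An intensive map from a composition vector to a growth rate (h^-1).

    Subclasses implement :meth:`_raw` on the *normalized* composition; the
    public :meth:`mu_d` first projects its argument onto the simplex, so
    every subclass is intensive by construction (``mu_d(a*phi) == mu_d(phi)``
    for any ``a > 0``). This normalization is also the degree-0 homogeneous
    extension used for numeric differentiation.
    """

    def mu_d(self, phi: np.ndarray, ids: Sequence[str]) -> float:
        phi = np.asarray(phi, dtype=float)
        total = phi.sum()
        if not np.isfinite(total) or total <= 0:
            raise NumericsError("composition must have a positive, finite sum")
        return self._raw(phi / total, ids)

    def _raw(self, phi: np.ndarray, ids: Sequence[str]) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class MonodGrowth(GrowthFunction):
    """Monod (hyperbolic) growth on the summed mass fraction of a target set.

    ``mu_d = mu_max * phi_O / (phi_half + phi_O)`` where ``phi_O`` is the
    summed normalized mass fraction of the proteins in ``target``.
    """

    mu_max: float
    phi_half: float
    target: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", frozenset(self.target))
        if self.mu_max <= 0 or self.phi_half <= 0:
            raise ConfigurationError("MonodGrowth: mu_max and phi_half must be > 0")

    def _raw(self, phi: np.ndarray, ids: Sequence[str]) -> float:
        mask = np.fromiter((i in self.target for i in ids), dtype=bool, count=len(ids))
        phi_o = float(phi[mask].sum())
        return self.mu_max * phi_o / (self.phi_half + phi_o)


@dataclass(frozen=True)
class LogLinearGrowth(GrowthFunction):
    """Log-linear growth surface with prescribed GCCs at a reference point.

    ``mu_d(phi) = mu0 * prod_i (phi_i / phi0_i)**gcc_i``. This is the
    canonical intensive surface whose logarithmic sensitivities at ``phi0``
    equal the supplied GCC vector exactly (intensivity requires the GCCs to
    sum to zero, which is validated). It is used to simulate models that are
    specified by ``(mu0, gcc)`` rather than by a mechanistic growth curve.
    """

    mu0: float
    phi0: tuple[float, ...]
    gcc: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi0", tuple(float(x) for x in self.phi0))
        object.__setattr__(self, "gcc", tuple(float(x) for x in self.gcc))
        if self.mu0 <= 0:
            raise ConfigurationError("LogLinearGrowth: mu0 must be > 0")
        if len(self.phi0) != len(self.gcc):
            raise ConfigurationError("LogLinearGrowth: phi0 and gcc lengths differ")
        if abs(sum(self.gcc)) > 1e-8:
            raise ConfigurationError(
                "LogLinearGrowth: GCCs must sum to zero for an intensive surface"
            )

    def _raw(self, phi: np.ndarray, ids: Sequence[str]) -> float:
        phi0 = np.asarray(self.phi0)
        gcc = np.asarray(self.gcc)
        if np.any(phi <= 0):
            raise NumericsError("LogLinearGrowth: composition left the positive orthant")
        return float(self.mu0 * np.exp(gcc @ np.log(phi / phi0)))


@dataclass(frozen=True)
class LinearizedGrowth(GrowthFunction):
    """First-order intensive growth surface with prescribed GCCs.

    ``mu_d(phi) = mu0 * (1 + sum_j C_j (psi_j - phi0_j) / phi0_j)`` with
    ``psi = phi / sum(phi)``. Like :class:`LogLinearGrowth` its logarithmic
    sensitivities at ``phi0`` equal the supplied GCC vector exactly, but it
    remains defined (and keeps a restoring synthesis flux) for the
    transient negative-mass-fraction excursions the stochastic integrator
    tolerates, where a log surface would collapse. It is the default
    surface for models specified by ``(mu0, gcc)``.
    """

    mu0: float
    phi0: tuple[float, ...]
    gcc: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi0", tuple(float(x) for x in self.phi0))
        object.__setattr__(self, "gcc", tuple(float(x) for x in self.gcc))
        if self.mu0 <= 0:
            raise ConfigurationError("LinearizedGrowth: mu0 must be > 0")
        if len(self.phi0) != len(self.gcc):
            raise ConfigurationError("LinearizedGrowth: phi0 and gcc lengths differ")
        if abs(sum(self.gcc)) > 1e-8:
            raise ConfigurationError(
                "LinearizedGrowth: GCCs must sum to zero for an intensive surface"
            )

    def _raw(self, phi: np.ndarray, ids: Sequence[str]) -> float:
        phi0 = np.asarray(self.phi0)
        gcc = np.asarray(self.gcc)
        return float(self.mu0 * (1.0 + gcc @ ((phi - phi0) / phi0)))


# ---------------------------------------------------------------------------
# the cell model


@dataclass(frozen=True)
class CellModel:
    """A full cell: protein species, noise wiring, and a growth description.

    Growth may be given either mechanistically (a :class:`GrowthFunction`)
    or phenomenologically (``mu0`` plus per-protein GCCs); the latter is
    turned into a :class:`LogLinearGrowth` surface when trajectories are
    simulated.
    """

    proteins: tuple[ProteinSpec, ...]
    shared: tuple[SharedNoiseSpec, ...] = ()
    growth: GrowthFunction | None = None
    mu0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "proteins", tuple(self.proteins))
        object.__setattr__(self, "shared", tuple(self.shared))
        ids = [p.id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate protein ids")
        total_f = math.fsum(p.f for p in self.proteins)
        if abs(total_f - 1.0) > 1e-12:
            raise ConfigurationError(
                f"allocation fractions must sum to 1 (got {total_f!r})"
            )
        known = set(ids)
        for s in self.shared:
            for pid, _ in s.members:
                if pid not in known:
                    raise ConfigurationError(
                        f"shared source {s.id!r} references unknown protein {pid!r}"
                    )

    # -- convenience views -------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.proteins)

    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def f(self) -> np.ndarray:
        return np.array([p.f for p in self.proteins])

    def index(self, protein_id: str) -> int:
        try:
            return self.ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def gcc_vector(self) -> np.ndarray | None:
        """Explicit per-protein GCCs, or None if any are missing."""
        vals = [p.gcc for p in self.proteins]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    def growth_surface(self) -> GrowthFunction:
        """The growth function used for simulation.

        Returns the mechanistic growth function when present; otherwise the
        first-order intensive surface built from ``(mu0, gcc)``.
        """
        if self.growth is not None:
            return self.growth
        gcc = self.gcc_vector()
        if self.mu0 is None or gcc is None:
            raise ConfigurationError(
                "model needs either a growth function or (mu0 + per-protein GCCs)"
            )
        return LinearizedGrowth(mu0=self.mu0, phi0=tuple(self.f), gcc=tuple(gcc))


@dataclass(frozen=True)
class SteadyState:
    """Zero-noise fixed point: mean composition and mean growth rate."""

    phi0: np.ndarray
    mu0: float


@dataclass(frozen=True)
class ControlAnalysis:
    """Paired GCC/FCC vectors with sum-rule residuals.

    ``fcc_i = gcc_i + phi0_i``; the residuals report ``sum(gcc)`` (ideally 0)
    and ``sum(fcc) - 1`` (ideally 0). ``phiH`` is the summed mass fraction
    of non-metabolic proteins when flags were provided, else ``nan``.
    """

    gcc: np.ndarray
    fcc: np.ndarray
    phiH: float
    gcc_sum_residual: float
    fcc_sum_residual: float


# ---------------------------------------------------------------------------
# operations


def steady_state(model: CellModel) -> SteadyState:
    """Mean composition and growth rate of the model.

    With zero-mean noise, stationarity of the dilution balance gives
    ``pi_0,i = f_i mu_0 = mu_0 phi_0,i``, hence ``phi0 = f`` exactly; the
    mean growth rate is the growth function evaluated there (or the supplied
    ``mu0``).
    """
    phi0 = model.f
    if model.growth is not None:
        mu0 = model.growth.mu_d(phi0, model.ids)
    elif model.mu0 is not None:
        mu0 = float(model.mu0)
    else:
        raise ConfigurationError("model carries neither a growth function nor mu0")
    return SteadyState(phi0=phi0, mu0=mu0)


def gcc_numeric(
    growth: GrowthFunction,
    phi0: np.ndarray,
    ids: Sequence[str],
    rel_step: float = 1e-5,
) -> np.ndarray:
    """Growth-control coefficients by central differencing.

    Computes the logarithmic sensitivity ``(phi_i / mu_d) dmu_d/dphi_i`` of
    the degree-0 homogeneous extension ``mu_d(phi / sum(phi))`` at ``phi0``,
    by a central difference in log-composition with relative step
    ``rel_step``. By Euler's theorem for degree-0 homogeneity the result
    sums to zero (up to differencing error).
    """
    phi0 = np.asarray(phi0, dtype=float)
    mu_ref = growth.mu_d(phi0, ids)
    if not np.isfinite(mu_ref) or mu_ref <= 0:
        raise NumericsError("growth rate must be positive and finite at phi0")
    gcc = np.empty(len(phi0))
    for i in range(len(phi0)):
        if phi0[i] == 0.0:
            gcc[i] = 0.0
            continue
        up = phi0.copy()
        dn = phi0.copy()
        up[i] = phi0[i] * math.exp(rel_step)
        dn[i] = phi0[i] * math.exp(-rel_step)
        mu_up = growth.mu_d(up, ids)
        mu_dn = growth.mu_d(dn, ids)
        if not (np.isfinite(mu_up) and np.isfinite(mu_dn) and mu_up > 0 and mu_dn > 0):
            raise NumericsError(f"non-finite growth rate while perturbing index {i}")
        gcc[i] = (math.log(mu_up) - math.log(mu_dn)) / (2.0 * rel_step)
    return gcc


def monod_log_slope(mu_max: float, phi_half: float, phi_O: float) -> float:
    """One-dimensional logarithmic slope of the Monod curve.

    ``d ln(mu) / d ln(phi_O) = phi_half / (phi_half + phi_O)`` for
    ``mu = mu_max phi_O / (phi_half + phi_O)``. This treats the curve as a
    one-dimensional dose–response (expression level in, growth rate out) and
    is the estimator used to assign the operon's growth-control coefficient;
    it differs from the degree-0-extension partial derivative by a factor
    ``(1 - phi_O)``.
    """
    if phi_O <= 0:
        raise ConfigurationError("monod_log_slope: phi_O must be > 0")
    if mu_max <= 0 or phi_half <= 0:
        raise ConfigurationError("monod_log_slope: mu_max and phi_half must be > 0")
    return phi_half / (phi_half + phi_O)


def gcc_fcc_convert(
    phi0: np.ndarray,
    gcc: np.ndarray | None = None,
    fcc: np.ndarray | None = None,
    nonmetabolic: np.ndarray | None = None,
) -> ControlAnalysis:
    """Convert between growth- and flux-control coefficients.

    Exactly one of ``gcc``/``fcc`` must be given; the other is filled via
    ``C_i^mu = C_i^J - phi_0,i``. Sum-rule residuals are reported, never
    raised: real models carry rounding error and the caller decides what is
    acceptable.
    """
    phi0 = np.asarray(phi0, dtype=float)
    if (gcc is None) == (fcc is None):
        raise ConfigurationError("supply exactly one of gcc or fcc")
    if gcc is not None:
        gcc = np.asarray(gcc, dtype=float)
        if gcc.shape != phi0.shape:
            raise ConfigurationError("gcc and phi0 must have the same length")
        fcc = gcc + phi0
    else:
        fcc = np.asarray(fcc, dtype=float)
        if fcc.shape != phi0.shape:
            raise ConfigurationError("fcc and phi0 must have the same length")
        gcc = fcc - phi0
    phiH = float(phi0[np.asarray(nonmetabolic, bool)].sum()) if nonmetabolic is not None else float("nan")
    return ControlAnalysis(
        gcc=gcc,
        fcc=fcc,
        phiH=phiH,
        gcc_sum_residual=float(gcc.sum()),
        fcc_sum_residual=float(fcc.sum() - 1.0),
    )


def nonmetabolic_sector(model: CellModel) -> tuple[float, float]:
    """Mass of the non-metabolic sector and the control it displaces.

    Non-metabolic proteins have zero flux control, hence GCC ``-phi_h``; the
    zero-sum rule then forces the metabolic sector to carry positive control
    equal to the flagged mass fraction ``phi_H``. Returns
    ``(phi_H, residual_metabolic_control)`` — the two are equal by the sum
    rule, and both are returned for readability at call sites.
    """
    phiH = math.fsum(p.f for p in model.proteins if p.nonmetabolic)
    return phiH, phiH


def make_two_protein_toy(
    gcc_Y: float = 0.25,
    phi0_Y: float = 0.33,
    mu0: float = 1.0,
    theta: float = 0.5,
    beta: float | None = None,
) -> CellModel:
    """The two-protein toy cell: a focal enzyme Y and the rest-of-proteome X.

    Defaults: ``C_Y^mu = 0.25`` (X carries ``-0.25`` by the zero-sum rule),
    ``phi_0,Y = 0.33``, ``mu_0 = 1`` /h, both noise sources with amplitude
    ``theta = 0.5`` and reversion rate ``beta = 4 mu_0``.
    """
    if beta is None:
        beta = 4.0 * mu0
    phi0_X = 1.0 - phi0_Y
    return CellModel(
        proteins=(
            ProteinSpec("X", phi0_X, OUNoiseSpec("N_X", theta, beta), gcc=-gcc_Y),
            ProteinSpec("Y", phi0_Y, OUNoiseSpec("N_Y", theta, beta), gcc=gcc_Y),
        ),
        mu0=mu0,
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Used when comparing computed control coefficients against printed
    two-significant-figure values (e.g. 0.0625 -> 0.063).
    """
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
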