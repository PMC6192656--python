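"""Assembly of the many-protein model with a lac-operon reporter construct.

The model couples a large synthetic background proteome (emulating the
abundance and noise structure of genome-scale single-cell *E. coli*
datasets: a broad log-normal abundance spectrum with a CV-versus-abundance
law that has an intrinsic ``1/n`` limb and an extrinsic floor) to a
three-gene lac operon (LacY, LacZ and a GFP reporter) that limits growth
through a Monod curve.

Three named growth conditions place the operon at mass fractions
``phi_O / phi_half = 0.3, 1.3, 15`` on the curve ``mu0 = mu_max * phi_O /
(phi_half + phi_O)`` with ``mu_max = 0.8`` /h and ``phi_half = 0.005``; the
operon's growth-control coefficient at each point is the one-dimensional
logarithmic slope of the curve, giving 0.77, 0.43 and 0.063.

Growth-control coefficients of the background respect the zero-sum rule:
~25% of the proteome mass is assigned to a non-metabolic sector (GCC
``-phi_h`` each), GFP is non-metabolic, LacY and LacZ split the remaining
operon control equally, and the metabolic background receives
mass-weighted random scores shifted (proportionally to mass) so the grand
total is exactly zero.

Noise amplitudes are fitted so that every lac protein has CV 0.15, the
shared operon source amplitude is 1.5x the GFP private amplitude, and all
background CVs match the table; all reversion rates are ``4 * mu_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CellModel,
    ConfigurationError,
    MonodGrowth,
    OUNoiseSpec,
    ProteinSpec,
    SharedNoiseSpec,
    monod_log_slope,
)
from .linear import noise_amplitudes_from_cvs

__all__ = [
    "GrowthCondition",
    "CONDITIONS",
    "generate_background_proteome",
    "read_proteome_tsv",
    "write_proteome_tsv",
    "add_lac_construct",
    "assign_gccs",
    "fit_noise",
    "build",
    "LAC_IDS",
    "OPERON_SOURCE_ID",
]

LAC_IDS = ("lacY", "lacZ", "gfp")
OPERON_SOURCE_ID = "N_O"

MU_MAX = 0.8  # h^-1
PHI_HALF = 0.005
BETA_DEFAULT = 4.0 * MU_MAX  # all reversion rates


@dataclass(frozen=True)
class GrowthCondition:
    """One operating point on the lac Monod curve."""

    name: str
    phi_ratio: float  # phi_O / phi_half
    mu_max: float = MU_MAX
    phi_half: float = PHI_HALF

    @property
    def phi_O(self) -> float:
        return self.phi_ratio * self.phi_half

    @property
    def mu0(self) -> float:
        return self.mu_max * self.phi_O / (self.phi_half + self.phi_O)

    @property
    def gcc_O(self) -> float:
        return monod_log_slope(self.mu_max, self.phi_half, self.phi_O)


CONDITIONS = {
    "slow": GrowthCondition("slow", 0.3),
    "intermediate": GrowthCondition("intermediate", 1.3),
    "fast": GrowthCondition("fast", 15.0),
}


def get_condition(name: str) -> GrowthCondition:
    try:
        return CONDITIONS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown condition {name!r}; choose from {sorted(CONDITIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# background proteome


def generate_background_proteome(
    n_species: int = 1018,
    seed: int = 0,
    log10_abundance_mean: float = 1.5,
    log10_abundance_sd: float = 1.0,
    abundance_range: tuple[float, float] = (0.1, 1e4),
    cv_law_a: float = 1.0,
    cv_law_b: float = 0.01,
    cv_scatter_log10_sd: float = 0.2,
) -> pd.DataFrame:
    """Synthetic background proteome table.

    Mean abundances are log-normal (log10 scale), truncated to
    ``abundance_range`` — the span of copy numbers covered by genome-scale
    single-cell proteome surveys (about 0.1 to 1e4 per cell). Without the
    truncation an unbounded tail occasionally hands one species an
    unrealistically large share of the proteome mass, which no measured
    bacterial proteome shows. CVs follow the phenomenological law
    ``eta^2 = a / <n> + b`` — Poisson-like intrinsic noise at low copy
    number, an extrinsic floor ``b`` at high abundance — with log-normal
    scatter around the law. The default floor (CV 10% for abundant
    proteins) keeps the proteome-wide noise load ``sum_j phi_j^2 eta_j^2``
    of order 1e-4, the regime in which the reporter's own noise modes are
    visible against the background dilution mode rather than swamped by
    it; see the methods note for the calibration argument. Deterministic
    under ``seed``.

    Columns: ``id, mean_abundance, cv, nonmetabolic`` (flag filled later by
    :func:`assign_gccs`).
    """
    if n_species < 2:
        raise ConfigurationError("need at least two background species")
    if cv_law_a < 0 or cv_law_b < 0 or log10_abundance_sd <= 0:
        raise ConfigurationError("invalid abundance/CV distribution parameters")
    lo, hi = abundance_range
    if not (0 < lo < hi):
        raise ConfigurationError("invalid abundance range")
    rng = np.random.default_rng(seed)
    abundance = 10.0 ** rng.normal(log10_abundance_mean, log10_abundance_sd, n_species)
    # truncate by redraw so the in-range shape is preserved
    for _ in range(1000):
        bad = (abundance < lo) | (abundance > hi)
        if not bad.any():
            break
        abundance[bad] = 10.0 ** rng.normal(
            log10_abundance_mean, log10_abundance_sd, int(bad.sum())
        )
    else:
        raise ConfigurationError("abundance range too narrow for the distribution")
    eta2 = (cv_law_a / abundance + cv_law_b) * 10.0 ** rng.normal(
        0.0, cv_scatter_log10_sd, n_species
    )
    width = len(str(n_species))
    return pd.DataFrame(
        {
            "id": [f"bg{j + 1:0{width}d}" for j in range(n_species)],
            "mean_abundance": abundance,
            "cv": np.sqrt(eta2),
            "nonmetabolic": False,
        }
    )


def read_proteome_tsv(path: str | Path) -> pd.DataFrame:
    """Read a user-supplied proteome table (columns id, mean_abundance, cv,
    optional nonmetabolic); validates positivity and id uniqueness."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "mean_abundance", "cv"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"proteome TSV must have columns {sorted(required)}")
    if "nonmetabolic" not in df.columns:
        df["nonmetabolic"] = False
    df["nonmetabolic"] = df["nonmetabolic"].astype(bool)
    if df["id"].duplicated().any():
        raise ConfigurationError("duplicate protein ids in proteome TSV")
    if (df["mean_abundance"] <= 0).any() or (df["cv"] <= 0).any():
        raise ConfigurationError("abundances and CVs must be positive")
    return df.reset_index(drop=True)


def write_proteome_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assembly steps


def add_lac_construct(table: pd.DataFrame, condition: GrowthCondition) -> pd.DataFrame:
    """Attach the three-gene operon and derive all mass fractions.

    The operon mass ``phi_O`` is shared equally among LacY, LacZ and GFP;
    background fractions fill the remaining ``1 - phi_O`` in the table's
    abundance proportions. Returns a table with a ``mass_fraction`` column
    summing to one and an ``is_lac`` flag.
    """
    if condition.phi_O >= 1.0:
        raise ConfigurationError("operon mass fraction must be below 1")
    if any(pid in set(table["id"]) for pid in LAC_IDS):
        raise ConfigurationError("proteome table already contains lac ids")
    bg = table.copy()
    bg["mass_fraction"] = (
        (1.0 - condition.phi_O) * bg["mean_abundance"] / bg["mean_abundance"].sum()
    )
    bg["is_lac"] = False
    lac = pd.DataFrame(
        {
            "id": list(LAC_IDS),
            "mean_abundance": np.nan,
            "cv": np.nan,
            "nonmetabolic": [False, False, True],
            "mass_fraction": condition.phi_O / 3.0,
            "is_lac": True,
        }
    )
    out = pd.concat([bg, lac], ignore_index=True)
    out["mass_fraction"] /= out["mass_fraction"].sum()
    return out


def assign_gccs(
    table: pd.DataFrame,
    condition: GrowthCondition,
    nonmetabolic_mass_target: float = 0.25,
    seed: int = 0,
    gcc_O_override: float | None = None,
) -> pd.DataFrame:
    """Assign growth-control coefficients under the zero-sum rule.

    Background proteins enter the non-metabolic sector in random order until
    its mass first reaches the target; each gets GCC ``-phi_h``. GFP is
    non-metabolic (GCC ``-phi_G``); LacY and LacZ each carry
    ``(C_O - C_G) / 2`` where ``C_O`` is the operon GCC from the Monod
    log-slope (or the override). Remaining metabolic proteins draw raw
    scores ``mass * Exponential(1)`` — larger proteins tend to carry larger
    control — then receive a mass-proportional shift so the grand total is
    exactly zero. (In the slow condition the operon holds more control than
    the non-metabolic sector displaces, so the metabolic background must
    carry net *negative* control; the shift handles either sign.)
    """
    if not (0.0 < nonmetabolic_mass_target < 1.0):
        raise ConfigurationError("nonmetabolic mass target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    df = table.copy().reset_index(drop=True)
    phi = df["mass_fraction"].to_numpy()
    is_lac = df["is_lac"].to_numpy()

    # random H assignment among background proteins
    bg_idx = np.flatnonzero(~is_lac)
    order = rng.permutation(bg_idx)
    h_mass = 0.0
    nonmet = df["nonmetabolic"].to_numpy().copy()
    nonmet[bg_idx] = False
    for j in order:
        if h_mass >= nonmetabolic_mass_target:
            break
        nonmet[j] = True
        h_mass += phi[j]
    df["nonmetabolic"] = nonmet
    df.loc[df["id"] == "gfp", "nonmetabolic"] = True

    gcc = np.zeros(len(df))
    nonmet = df["nonmetabolic"].to_numpy()
    gcc[nonmet] = -phi[nonmet]

    gcc_O = condition.gcc_O if gcc_O_override is None else float(gcc_O_override)
    i_g = int(np.flatnonzero(df["id"] == "gfp")[0])
    gcc_yz = (gcc_O - gcc[i_g]) / 2.0
    for pid in ("lacY", "lacZ"):
        gcc[int(np.flatnonzero(df["id"] == pid)[0])] = gcc_yz

    met = np.flatnonzero(~nonmet & ~is_lac)
    if met.size == 0:
        raise ConfigurationError("no metabolic background proteins left")
    raw = phi[met] * rng.exponential(1.0, size=met.size)
    needed = -(gcc.sum())  # what the metabolic background must sum to
    mass_met = phi[met].sum()
    gcc[met] = raw + phi[met] * (needed - raw.sum()) / mass_met
    # remove the last eps of rounding error, spread by mass
    gcc[met] -= phi[met] * gcc.sum() / mass_met
    df["gcc"] = gcc
    return df


def fit_noise(
    table: pd.DataFrame,
    condition: GrowthCondition,
    lac_cv_target: float = 0.15,
    operon_theta_ratio: float = 1.5,
    beta: float = BETA_DEFAULT,
) -> tuple[np.ndarray, float]:
    """Fit all source amplitudes to the CV targets.

    Constraints: every lac protein has CV ``lac_cv_target``; the shared
    operon source amplitude is ``operon_theta_ratio`` times the GFP private
    amplitude; background CVs equal the table's ``cv`` column. All reversion
    rates are ``beta``. Returns ``(private_thetas, operon_theta)`` aligned
    with the table rows.
    """
    phi0 = table["mass_fraction"].to_numpy()
    ids = list(table["id"])
    n = len(ids)
    is_lac = table["is_lac"].to_numpy()
    targets = np.where(is_lac, lac_cv_target, table["cv"].to_numpy(float))

    # sources: one private per protein, plus the shared operon source
    wiring = np.vstack([np.eye(n), np.zeros((1, n))])
    for pid in LAC_IDS:
        wiring[n, ids.index(pid)] = 1.0 / 3.0
    betas = np.full(n + 1, beta)
    ties = [(n, ids.index("gfp"), operon_theta_ratio)]
    thetas = noise_amplitudes_from_cvs(
        phi0=phi0,
        mu0=condition.mu0,
        betas=betas,
        wiring=wiring,
        target_cv=targets,
        amplitude_ties=ties,
        protein_ids=ids + [OPERON_SOURCE_ID],
    )
    return thetas[:n], float(thetas[n])


def build(
    condition_name: str,
    seed: int = 0,
    table: pd.DataFrame | None = None,
    n_background: int = 1018,
    nonmetabolic_mass_target: float = 0.25,
    lac_cv_target: float = 0.15,
    operon_theta_ratio: float = 1.5,
    gcc_O_override: float | None = None,
) -> CellModel:
    """Assemble a fully parameterized many-protein cell model.

    Composes proteome generation (or a user table), the lac construct, GCC
    assignment and the noise fit. All randomness flows from ``seed`` through
    spawned child streams, so the same seed gives an identical model.
    """
    condition = get_condition(condition_name)
    seq = np.random.SeedSequence(seed)
    s_table, s_gcc = (int(c.generate_state(1)[0] % (2**31)) for c in seq.spawn(2))
    if table is None:
        table = generate_background_proteome(n_background, seed=s_table)
    df = add_lac_construct(table, condition)
    df = assign_gccs(
        df,
        condition,
        nonmetabolic_mass_target=nonmetabolic_mass_target,
        seed=s_gcc,
        gcc_O_override=gcc_O_override,
    )
    thetas, theta_O = fit_noise(
        df,
        condition,
        lac_cv_target=lac_cv_target,
        operon_theta_ratio=operon_theta_ratio,
    )
    f = df["mass_fraction"].to_numpy().copy()
    f[-1] += 1.0 - math.fsum(f)  # absorb rounding so sum(f) == 1 exactly
    proteins = tuple(
        ProteinSpec(
            id=row.id,
            f=float(f[j]),
            private_noise=OUNoiseSpec(f"N_{row.id}", float(thetas[j]), BETA_DEFAULT),
            gcc=float(row.gcc),
            nonmetabolic=bool(row.nonmetabolic),
            operon="lac" if row.is_lac else None,
        )
        for j, row in enumerate(df.itertuples())
    )
    shared = (
        SharedNoiseSpec(
            id="O",
            noise=OUNoiseSpec(OPERON_SOURCE_ID, theta_O, BETA_DEFAULT),
            members=tuple((pid, 1.0 / 3.0) for pid in LAC_IDS),
        ),
    )
    return CellModel(proteins=proteins, shared=shared, mu0=condition.mu0)
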