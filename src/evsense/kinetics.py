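"""Two-state (conformational-change) binding kinetics for SPR sensorgrams.

The antigen--antibody interaction is modelled by the scheme

    A + B <-> AB <-> AB*

where the encounter complex AB converts to a more stable complex AB*.
With analyte concentration ``C`` (molar), free-site density
``rmax - AB - AB*`` and the response ``R = AB + AB*`` (response units),
the mass-action ODE system is

    d[AB]/dt  = ka1*C*(rmax - AB - AB*) - kd1*AB - ka2*AB + kd2*AB*
    d[AB*]/dt = ka2*AB - kd2*AB*

During dissociation ``C = 0`` and the system is linear with matrix
``[[-(kd1+ka2), kd2], [ka2, -kd2]]``; an exact eigen-decomposition
solution is provided as an oracle and as a fast model kernel for fitting.

Stepwise equilibrium constants are KD1 = kd1/ka1 (M), KD2 = kd2/ka2
(dimensionless); the total equilibrium dissociation constant is their
product KD_total = KD1*KD2 (M).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import linregress

AVOGADRO = 6.02214076e23

__all__ = [
    "AVOGADRO",
    "TwoStateRateSet",
    "InjectionProtocol",
    "Sensorgram",
    "KineticFitResult",
    "EquilibriumConstants",
    "LinearityFit",
    "IdentifiabilityError",
    "FitError",
    "particles_to_molar",
    "simulate_two_state",
    "dissociation_closed_form",
    "fit_two_state",
    "stepwise_constants",
    "dissociation_linearity",
]


class IdentifiabilityError(ValueError):
    """Raised when the data carry no information about the parameters."""


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best attempt."""

    def __init__(self, message: str, best_result: "KineticFitResult | None" = None):
        super().__init__(message)
        self.best_result = best_result


@dataclass(frozen=True)
class TwoStateRateSet:
    """Rate constants of the two-state model for one antibody channel.

    Parameters
    ----------
    ka1 : float
        Association rate of the encounter step (M^-1 s^-1).
    kd1 : float
        Dissociation rate of the encounter step (s^-1).
    ka2 : float
        Forward conformational-change rate (s^-1).
    kd2 : float
        Reverse conformational-change rate (s^-1).
    rmax : float
        Saturation response (response units).
    channel : str
        Channel label, e.g. ``"anti-CD9"``.
    """

    ka1: float
    kd1: float
    ka2: float
    kd2: float
    rmax: float = 100.0
    channel: str = "custom"

    def __post_init__(self) -> None:
        for name in ("ka1", "kd1", "ka2", "kd2", "rmax"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def KD1(self) -> float:
        """Stepwise equilibrium dissociation constant kd1/ka1 (M)."""
        return self.kd1 / self.ka1

    @property
    def KD2(self) -> float:
        """Stepwise equilibrium constant kd2/ka2 (dimensionless)."""
        return self.kd2 / self.ka2

    @property
    def KD_total(self) -> float:
        """Total equilibrium dissociation constant KD1*KD2 (M)."""
        return self.KD1 * self.KD2


@dataclass(frozen=True)
class InjectionProtocol:
    """Injection timing for one sensorgram.

    Defaults follow a 90 s analyte contact followed by a 300 s buffer
    (dissociation) phase at a 5 uL/min flow rate.
    """

    analyte_concentration: float  # molar
    association_duration: float = 90.0  # s
    dissociation_duration: float = 300.0  # s
    sampling_interval: float = 1.0  # s
    flow_rate: float = 5.0  # uL/min, metadata only

    def __post_init__(self) -> None:
        if self.association_duration <= 0 or self.dissociation_duration <= 0:
            raise ValueError("phase durations must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.analyte_concentration < 0:
            raise ValueError("analyte_concentration must be non-negative")


@dataclass
class Sensorgram:
    """A phased SPR time series at a single analyte concentration."""

    time: np.ndarray  # s, strictly increasing
    response: np.ndarray  # response units
    phase: np.ndarray  # per-point: baseline | association | dissociation
    concentration: float  # molar
    channel: str = "custom"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time must be a 1-D grid with at least two points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (len(self.time) == len(self.response) == len(self.phase)):
            raise ValueError("time, response and phase must have equal length")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response must be finite")

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == name


class EquilibriumConstants(NamedTuple):
    """Stepwise and total equilibrium dissociation constants."""

    KD1: float  # M
    KD2: float  # dimensionless
    KD_total: float  # M


@dataclass
class KineticFitResult:
    """Outcome of a global two-state fit."""

    rates: TwoStateRateSet
    stderr: dict[str, float]
    rss: float
    converged: bool
    n_sensorgrams: int
    n_points: int
    fixed: dict[str, float]
    poorly_identified: bool = False

    @property
    def constants(self) -> EquilibriumConstants:
        return stepwise_constants(self.rates)


def particles_to_molar(c_particles: float) -> float:
    """Convert a particle number concentration (mL^-1) to molar.

    ``M = c * 1000 / N_A`` — particles per mL to particles per litre,
    then to moles per litre.
    """
    if c_particles < 0:
        raise ValueError("particle concentration must be non-negative")
    return c_particles * 1000.0 / AVOGADRO


# ---------------------------------------------------------------------------
# linear-system kernels


def _phase_system(rates: TwoStateRateSet, conc: float):
    """Matrix A and constant b of d[x]/dt = A x + b for one phase."""
    kobs = rates.ka1 * conc
    A = np.array(
        [
            [-(kobs + rates.kd1 + rates.ka2), rates.kd2 - kobs],
            [rates.ka2, -rates.kd2],
        ]
    )
    b = np.array([kobs * rates.rmax, 0.0])
    return A, b


def _linear_response(A: np.ndarray, b: np.ndarray, x0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact solution x(t) of dx/dt = A x + b with x(0)=x0, for 2x2 A.

    Uses the eigen-decomposition x(t) = x_ss + V e^{L t} V^{-1} (x0-x_ss);
    a defective (repeated-eigenvalue) A falls back to the matrix
    exponential per time point, which realizes the limiting form.
    """
    t = np.asarray(t, dtype=float)
    x_ss = np.linalg.solve(A, -b)
    dx0 = x0 - x_ss
    lam, V = np.linalg.eig(A)
    # near-defective: eigenvector matrix ill-conditioned
    if np.linalg.cond(V) > 1e8:
        out = np.empty((len(t), 2))
        for i, ti in enumerate(t):
            out[i] = x_ss + expm(A * ti) @ dx0
        return out
    c = np.linalg.solve(V, dx0)
    # (n_t, 2) trajectories; complex pairs cancel to real
    traj = (V @ (np.exp(np.outer(lam, t)) * c[:, None])).T
    return x_ss[None, :] + np.real(traj)


def _two_state_model(
    rates: TwoStateRateSet, protocol: InjectionProtocol
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact two-phase trajectory on the protocol grid: (t, phase, response)."""
    t, phase = _protocol_grid(protocol)
    assoc = phase == "association"
    A_on, b_on = _phase_system(rates, protocol.analyte_concentration)
    x_assoc = _linear_response(A_on, b_on, np.zeros(2), t[assoc])
    t0_diss = protocol.association_duration
    x_end = _linear_response(A_on, b_on, np.zeros(2), np.array([t0_diss]))[0]
    resp = np.empty(len(t))
    resp[assoc] = x_assoc.sum(axis=1)
    if (~assoc).any():
        A_off, b_off = _phase_system(rates, 0.0)
        x_diss = _linear_response(A_off, b_off, x_end, t[~assoc] - t0_diss)
        resp[~assoc] = x_diss.sum(axis=1)
    return t, phase, resp


def _protocol_grid(protocol: InjectionProtocol) -> tuple[np.ndarray, np.ndarray]:
    total = protocol.association_duration + protocol.dissociation_duration
    n = int(np.floor(total / protocol.sampling_interval + 1e-9)) + 1
    t = np.arange(n) * protocol.sampling_interval
    phase = np.where(t <= protocol.association_duration, "association", "dissociation")
    return t, phase.astype(object)


def simulate_two_state(
    rates: TwoStateRateSet,
    protocol: InjectionProtocol,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    bulk_shift: float = 0.0,
) -> Sensorgram:
    """Integrate the two-state ODE system over one injection cycle.

    Uses a stiff-capable adaptive integrator (LSODA) phase by phase and
    evaluates on the protocol's sampling grid.  The absolute tolerance is
    scaled by the steady-state response amplitude so that accuracy is
    amplitude-independent (responses span ten orders of magnitude between
    near-saturating and particle-derived analyte concentrations).
    ``bulk_shift`` is an optional additive constant applied during the
    association phase only (bulk refractive-index jump); the default 0
    treats sensorgrams as already double-referenced.
    """
    t, phase = _protocol_grid(protocol)
    C = protocol.analyte_concentration
    if C == 0.0:
        resp = np.zeros(len(t))
        return Sensorgram(t, resp, phase, C, rates.channel)

    A_on, b_on = _phase_system(rates, C)
    amplitude = float(np.sum(np.linalg.solve(A_on, -b_on)))
    atol = atol * max(abs(amplitude), 1e-300)

    def rhs(_t, x, conc):
        ab, abs_ = x
        free = rates.rmax - ab - abs_
        dab = rates.ka1 * conc * free - rates.kd1 * ab - rates.ka2 * ab + rates.kd2 * abs_
        dabs = rates.ka2 * ab - rates.kd2 * abs_
        return (dab, dabs)

    assoc = phase == "association"
    t_assoc = t[assoc]
    sol_on = solve_ivp(
        rhs,
        (0.0, protocol.association_duration),
        (0.0, 0.0),
        t_eval=None,
        dense_output=True,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        args=(C,),
    )
    if not sol_on.success:
        raise RuntimeError(f"association-phase integration failed: {sol_on.message}")
    x_assoc = sol_on.sol(t_assoc).T
    x_end = sol_on.sol(protocol.association_duration)
    sol_off = solve_ivp(
        rhs,
        (0.0, protocol.dissociation_duration),
        tuple(x_end),
        dense_output=True,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        args=(0.0,),
    )
    if not sol_off.success:
        raise RuntimeError(f"dissociation-phase integration failed: {sol_off.message}")
    resp = np.empty(len(t))
    resp[assoc] = x_assoc.sum(axis=1) + bulk_shift
    if (~assoc).any():
        x_diss = sol_off.sol(t[~assoc] - protocol.association_duration).T
        resp[~assoc] = x_diss.sum(axis=1)
    # guard tiny negative round-off
    np.clip(resp, 0.0, None, out=resp)
    return Sensorgram(t, resp, phase, C, rates.channel)


def dissociation_closed_form(
    rates: TwoStateRateSet,
    ab0: float,
    abstar0: float,
    t: float | np.ndarray,
) -> np.ndarray | float:
    """Exact total response AB(t)+AB*(t) of the buffer (C=0) phase.

    Solves the linear system with matrix ``[[-(kd1+ka2), kd2],
    [ka2, -kd2]]`` by eigen-decomposition; the repeated-eigenvalue case
    is handled by the matrix-exponential limiting form.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    A, b = _phase_system(rates, 0.0)
    x = _linear_response(A, b, np.array([ab0, abstar0]), t_arr)
    resp = x.sum(axis=1)
    return resp if np.ndim(t) else float(resp[0])


def dissociation_eigenvalues(rates: TwoStateRateSet) -> np.ndarray:
    """Eigenvalues of the dissociation-phase system matrix (both real, <= 0)."""
    A, _ = _phase_system(rates, 0.0)
    return np.sort(np.linalg.eigvals(A).real)


def stepwise_constants(rates: TwoStateRateSet) -> EquilibriumConstants:
    """Stepwise and total equilibrium dissociation constants.

    KD1 = kd1/ka1 (M), KD2 = kd2/ka2 (dimensionless),
    KD_total = KD1*KD2 (M).
    """
    if rates.ka1 == 0 or rates.ka2 == 0:
        raise ValueError("association rates must be non-zero")
    kd1 = rates.kd1 / rates.ka1
    kd2 = rates.kd2 / rates.ka2
    return EquilibriumConstants(kd1, kd2, kd1 * kd2)


# ---------------------------------------------------------------------------
# fitting

_PARAM_NAMES = ("ka1", "kd1", "ka2", "kd2", "rmax")


def _residuals(
    log_params: np.ndarray,
    free_names: Sequence[str],
    fixed: dict[str, float],
    sensorgrams: Sequence[Sensorgram],
    protocols: Sequence[InjectionProtocol],
    weights: Sequence[float],
    channel: str,
) -> np.ndarray:
    values = dict(fixed)
    values.update({n: 10.0**p for n, p in zip(free_names, log_params)})
    try:
        rates = TwoStateRateSet(channel=channel, **values)
    except ValueError:
        return np.full(sum(len(s.time) for s in sensorgrams), 1e6)
    out = []
    for s, proto, w in zip(sensorgrams, protocols, weights):
        _, _, model = _two_state_model(rates, proto)
        out.append((model - s.response) * w)
    return np.concatenate(out)


def _protocol_from_sensorgram(s: Sensorgram) -> InjectionProtocol:
    assoc = s.phase == "association"
    if not assoc.any() or assoc.all():
        raise ValueError("sensorgram must contain association and dissociation phases")
    t_assoc_end = s.time[assoc][-1]
    dt = float(np.median(np.diff(s.time)))
    return InjectionProtocol(
        analyte_concentration=s.concentration,
        association_duration=float(t_assoc_end),
        dissociation_duration=float(s.time[-1] - t_assoc_end),
        sampling_interval=dt,
    )


def fit_two_state(
    sensorgrams: Sequence[Sensorgram],
    fix: dict[str, float] | None = None,
    bounds: tuple[float, float] = (1e-8, 1e10),
    kd1_grid: tuple[float, float] = (1e-4, 1e-1),
    ka2_grid: tuple[float, float] = (1e-4, 1e-1),
    kd2_starts: tuple[float, ...] = (1e-6, 1e-4, 1e-2),
    grid_per_decade: int = 3,
    top_k: int = 12,
) -> KineticFitResult:
    """Global nonlinear least-squares fit of the two-state model.

    Parameters are optimized in log10 space within ``bounds`` (native
    units), with a multi-start strategy: a coarse grid (``grid_per_decade``
    points per decade) on kd1 and ka2 seeds candidate starts, the
    ``top_k`` best-scoring starts are refined, and ties are broken by
    lowest residual sum of squares then lowest parameter-vector norm.

    ``fix`` pins parameters at known values (e.g. ``{"rmax": 100.0}``
    when the saturation response is known from the ligand-capture level;
    at analyte concentrations far below KD1 only the product ka1*rmax is
    identifiable from the data, so rmax must be supplied independently).

    Residuals of each sensorgram are weighted by the inverse of its RMS
    response so that every concentration contributes comparably.
    """
    if not sensorgrams:
        raise ValueError("at least one sensorgram is required")
    channels = {s.channel for s in sensorgrams}
    if len(channels) > 1:
        raise ValueError(f"sensorgrams must share a channel, got {sorted(channels)}")
    channel = sensorgrams[0].channel
    fixed = dict(fix or {})
    for name in fixed:
        if name not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    free_names = [n for n in _PARAM_NAMES if n not in fixed]

    max_abs = max(float(np.max(np.abs(s.response))) for s in sensorgrams)
    if max_abs == 0.0 or all(np.ptp(s.response) == 0.0 for s in sensorgrams):
        raise IdentifiabilityError("flat/zero response carries no kinetic information")

    protocols = [_protocol_from_sensorgram(s) for s in sensorgrams]
    weights = []
    for s in sensorgrams:
        rms = float(np.sqrt(np.mean(s.response**2)))
        weights.append(1.0 / rms if rms > 0 else 1.0)

    n_conc = len({s.concentration for s in sensorgrams})
    poorly_identified = n_conc < 2

    # heuristic center: initial association slope ~ ka1*C*rmax
    s_hi = max(sensorgrams, key=lambda s: s.concentration)
    assoc = s_hi.phase == "association"
    t_a, r_a = s_hi.time[assoc], s_hi.response[assoc]
    k_early = min(max(3, len(t_a) // 10), len(t_a))
    slope0 = max(np.polyfit(t_a[:k_early], r_a[:k_early], 1)[0], 1e-30)
    rmax0 = fixed.get("rmax", 2.0 * max_abs)
    ka1_0 = np.clip(slope0 / (max(s_hi.concentration, 1e-300) * rmax0), *bounds)

    def grid(lo_hi):
        lo, hi = np.log10(lo_hi[0]), np.log10(lo_hi[1])
        n = int(round((hi - lo) * grid_per_decade)) + 1
        return np.logspace(lo, hi, n)

    starts = []
    base = {"ka1": float(ka1_0), "kd1": 1e-3, "ka2": 1e-2, "kd2": 1e-4, "rmax": rmax0}
    for kd1 in grid(kd1_grid):
        for ka2 in grid(ka2_grid):
            for kd2 in kd2_starts:
                cand = dict(base)
                cand["kd1"], cand["ka2"], cand["kd2"] = kd1, ka2, kd2
                starts.append(np.array([np.log10(cand[n]) for n in free_names]))

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    args = (free_names, fixed, sensorgrams, protocols, weights, channel)
    scored = []
    for x0 in starts:
        r = _residuals(x0, *args)
        scored.append((float(r @ r), x0))
    scored.sort(key=lambda p: p[0])

    best = None
    any_success = False
    for _, x0 in scored[:top_k]:
        try:
            res = least_squares(
                _residuals,
                np.clip(x0, lo, hi),
                args=args,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=4000,
            )
        except Exception:
            continue
        rss = float(res.fun @ res.fun)
        key = (rss, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
        any_success = any_success or res.success

    if best is None:
        raise FitError("all optimizer starts failed")
    res = best[1]
    # unbounded Levenberg-Marquardt polish: digs deeper into the shallow
    # valleys typical of near-zero-residual kinetic refits
    try:
        polished = least_squares(
            _residuals, res.x, args=args, method="lm", jac="3-point",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
        )
        if (float(polished.fun @ polished.fun) < float(res.fun @ res.fun)
                and np.all(polished.x >= lo) and np.all(polished.x <= hi)):
            res = polished
            any_success = any_success or polished.success
    except Exception:
        pass
    values = dict(fixed)
    values.update({n: 10.0**p for n, p in zip(free_names, res.x)})
    rates = TwoStateRateSet(channel=channel, **values)

    n_points = sum(len(s.time) for s in sensorgrams)
    dof = max(n_points - len(free_names), 1)
    rss = float(res.fun @ res.fun)
    stderr = {n: float("nan") for n in _PARAM_NAMES}
    try:
        JTJ = res.jac.T @ res.jac
        cov_log = np.linalg.pinv(JTJ) * (rss / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        for n, se in zip(free_names, se_log):
            stderr[n] = float(se * np.log(10.0) * values[n])
        for n in fixed:
            stderr[n] = 0.0
    except Exception:
        pass

    result = KineticFitResult(
        rates=rates,
        stderr=stderr,
        rss=rss,
        converged=bool(any_success),
        n_sensorgrams=len(sensorgrams),
        n_points=n_points,
        fixed=fixed,
        poorly_identified=poorly_identified,
    )
    if not any_success:
        raise FitError("no optimizer start converged", best_result=result)
    return result


# ---------------------------------------------------------------------------
# dissociation diagnostics


@dataclass
class LinearityFit:
    """ln(R0/R) vs t regression over the dissociation phase."""

    slope: float  # s^-1
    r_squared: float
    n_points: int
    truncated: bool = False


def dissociation_linearity(
    s: Sensorgram, window: tuple[float, float] | None = None
) -> LinearityFit:
    """Least-squares line through ln(R0/R(t)) vs t-t0 over dissociation.

    R0 is the response at the start of the post-injection phase; by
    construction the transformed series is 0 at t0.  Points at or after
    the first non-positive response are dropped and the fit flagged as
    truncated.  ``window`` restricts the fit to t-t0 within [lo, hi].
    """
    mask = s.phase == "dissociation"
    if not mask.any():
        raise ValueError("sensorgram has no dissociation phase")
    t = s.time[mask]
    r = s.response[mask]
    t0 = t[0]
    r0 = r[0]
    if r0 <= 0:
        raise ValueError("response at start of dissociation must be positive")
    truncated = False
    nonpos = np.nonzero(r <= 0)[0]
    if len(nonpos):
        t, r = t[: nonpos[0]], r[: nonpos[0]]
        truncated = True
    if window is not None:
        sel = (t - t0 >= window[0]) & (t - t0 <= window[1])
        t, r = t[sel], r[sel]
    if len(t) < 2:
        raise ValueError("too few positive dissociation points for a regression")
    y = np.log(r0 / r)
    x = t - t0
    fit = linregress(x, y)
    return LinearityFit(
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        n_points=len(t),
        truncated=truncated,
    )
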