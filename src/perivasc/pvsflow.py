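"""Quasi-steady Stokes flow of CSF in a deforming annular PVS.

The perivascular space is the annulus between a vessel of radius R_v(t)
(uniform along the vessel, time-dependent) and a fixed outer endfoot-tube
radius R_ast, of axial length L = 600 um.  The PVS cross-section area
follows the measured oscillation law

    A_pvs(t) = <A_pvs> (1 + <a_PT>/2 cos(2 pi t / <p_PP>)) - A_SMC,

with A_SMC = alpha * <A_pvs>_baseline a constant obstructed area
(alpha in {0, 25, 50 %}).  At the Womersley (<= 0.1) and Reynolds
(<= 3e-3) numbers of these flows, inertia is negligible and the flow is
quasi-steady Stokes.  Because the deformation is axially uniform, mass
conservation fixes the volume flux Q(y, t) = (L - y) dA/dt with the deep
end closed, and the axial velocity profile at each instant is the
classical annular Poiseuille profile between R_v(t) and R_ast.  The
pressure follows from the annular conductance with p = 0 at the surface
entrance.

Units: geometry in um, time in s, velocities in um/s, pressure in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

UM = 1e-6  # m per um

#: water viscosity at 35 C (Pa s); the rounded upper-estimate value used
#: for the dimensionless numbers is also exposed
MU_DEFAULT = 6.93e-4
MU_ROUNDED = 7.0e-4


@dataclass(frozen=True)
class FluidConstants:
    """CSF treated as water at 35 C."""

    mu: float = MU_DEFAULT   # Pa s
    rho: float = 1000.0      # kg/m^3, used only for dimensionless numbers

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")


@dataclass
class PVSModel:
    """Geometry, area-law parameters and fluid constants of one simulation.

    ``A_med`` is the median PVS cross-section area <A_pvs> (um^2),
    ``a_rel`` the median relative P–T amplitude of the area oscillation,
    ``period`` the median lumen P–P period (s), ``alpha`` the obstructed
    fraction of the baseline area (``A_baseline`` defaults to ``A_med``;
    in the full analysis it is the quiet-wakefulness median).
    """

    A_med: float
    a_rel: float
    period: float
    R_ast: float
    alpha: float = 0.0
    A_baseline: Optional[float] = None
    L: float = 600.0
    fluids: FluidConstants = field(default_factory=FluidConstants)

    def __post_init__(self) -> None:
        if self.A_baseline is None:
            self.A_baseline = self.A_med
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.a_rel < 0:
            raise ValueError("a_rel must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")
        a_min = self.A_med * (1 - self.a_rel / 2) - self.A_smc
        if a_min <= 0:
            raise ValueError("PVS collapses: min over t of A_pvs <= 0")
        a_max = self.A_med * (1 + self.a_rel / 2) - self.A_smc
        if a_max >= np.pi * self.R_ast ** 2:
            raise ValueError("A_pvs exceeds the outer cylinder cross "
                             "section; R_v would vanish")

    @property
    def A_smc(self) -> float:
        """Obstructed cross-section area A_SMC = alpha * <A>_baseline."""
        return self.alpha * self.A_baseline

    @classmethod
    def from_summary(cls, summary, R_ast: Optional[float] = None,
                     alpha: float = 0.0,
                     A_baseline: Optional[float] = None,
                     **kw) -> "PVSModel":
        """Build a model from a :class:`~perivasc.dynamics.BandSummary`.

        ``R_ast`` defaults to the summary's median endfoot-tube radius.
        """
        if R_ast is None:
            R_ast = summary.r_endfoot_med
        return cls(A_med=summary.A_med, a_rel=summary.a_rel,
                   period=summary.p_pp, R_ast=R_ast, alpha=alpha,
                   A_baseline=A_baseline, **kw)


def area_law(A_med: float, a_rel: float, period: float, t: np.ndarray,
             A_smc: float = 0.0, phase: float = 0.0) -> np.ndarray:
    """A_pvs(t) = <A>(1 + a_rel/2 cos(2 pi t / period + phase)) - A_SMC.

    ``phase`` shifts the oscillation start; the default starts at the
    area maximum (cos(0) = 1).  Transport analyses start at the median
    area (phase = -pi/2) so that sampled statistics are phase-neutral.
    """
    if a_rel < 0:
        raise ValueError("a_rel must be >= 0")
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.asarray(t, dtype=float)
    A = (A_med * (1 + a_rel / 2 * np.cos(2 * np.pi * t / period + phase))
         - A_smc)
    if np.any(A_med * (1 - a_rel / 2) - A_smc <= 0):
        raise ValueError("PVS collapses: A_pvs <= 0 at the trough")
    return A


def area_rate(A_med: float, a_rel: float, period: float, t: np.ndarray,
              phase: float = 0.0) -> np.ndarray:
    """dA_pvs/dt (um^2/s), analytic derivative of the area law."""
    t = np.asarray(t, dtype=float)
    w = 2 * np.pi / period
    return -A_med * a_rel / 2 * w * np.sin(w * t + phase)


def inner_radius(A_pvs: np.ndarray, R_ast: float) -> np.ndarray:
    """R_v(t) = sqrt(R_ast^2 - A_pvs/pi); R_ast is fixed."""
    A_pvs = np.asarray(A_pvs, dtype=float)
    if np.any(A_pvs >= np.pi * R_ast ** 2):
        raise ValueError("A_pvs must stay below pi R_ast^2")
    return np.sqrt(R_ast ** 2 - A_pvs / np.pi)


# ---------------------------------------------------------------------------
# Annular Poiseuille profile
# ---------------------------------------------------------------------------

def conductance_factor(R_v: float, R_ast: float) -> float:
    """M = R1^4 - R2^4 - (R1^2 - R2^2)^2 / ln(R1/R2) for the annulus
    (R2 = R_v inner, R1 = R_ast outer); Q = pi G M / (8 mu) for axial
    pressure gradient G = -dp/dy."""
    r1s, r2s = R_ast ** 2, R_v ** 2
    return (r1s ** 2 - r2s ** 2 - (r1s - r2s) ** 2
            / np.log(R_ast / R_v))


def _k_factor(R_v: float, R_ast: float) -> float:
    return (R_ast ** 2 - R_v ** 2) / np.log(R_ast / R_v)


def profile_shape(r: np.ndarray, R_v: float, R_ast: float) -> np.ndarray:
    """Annular Poiseuille axial profile normalized to unit mean.

    u(r)/u_mean = 2 [R1^2 - r^2 + k ln(r/R1)] / (R1^2 + R2^2 - k),
    k = (R1^2 - R2^2)/ln(R1/R2); no-slip at both walls.
    """
    r = np.asarray(r, dtype=float)
    k = _k_factor(R_v, R_ast)
    num = R_ast ** 2 - r ** 2 + k * np.log(r / R_ast)
    den = (R_ast ** 2 + R_v ** 2 - k) / 2.0
    return num / den


def peak_shape_factor(R_v: float, R_ast: float) -> float:
    """max_r u(r) / u_mean for the annular Poiseuille profile."""
    k = _k_factor(R_v, R_ast)
    r_m = np.sqrt(k / 2.0)
    return float(profile_shape(np.array([r_m]), R_v, R_ast)[0])


@dataclass
class FlowSolution:
    """Reduced (lubrication) solution of the oscillatory annular flow.

    ``u_mean`` is the cross-section mean axial velocity (um/s, positive
    into the brain), ``p`` the pressure (Pa, p(0, t) = 0), ``A`` the PVS
    area (um^2). ``u_peak`` is the pointwise maximum over (r, y, t) of
    the axial velocity magnitude, attained at y = 0.
    """

    y: np.ndarray            # um, 0 .. L
    t: np.ndarray            # s
    u_mean: np.ndarray       # (n_y, n_t) um/s
    p: np.ndarray            # (n_y, n_t) Pa
    A: np.ndarray            # (n_t,) um^2
    dA_dt: np.ndarray        # (n_t,) um^2/s
    R_v: np.ndarray          # (n_t,) um
    u_peak: float            # um/s
    model: PVSModel


def solve_pvs_flow(model: PVSModel, t_grid: Optional[np.ndarray] = None,
                   n_y: int = 121) -> FlowSolution:
    """Quasi-steady Stokes flow driven by the area law.

    Axially uniform deformation + closed deep end give the volume flux
    Q(y, t) = (L - y) dA/dt; u_mean = Q/A; the instantaneous radial
    profile is annular Poiseuille, whose conductance yields the axial
    pressure gradient integrated from p(0) = 0.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, model.period, 401)
    t_grid = np.asarray(t_grid, dtype=float)
    y = np.linspace(0.0, model.L, n_y)

    A = area_law(model.A_med, model.a_rel, model.period, t_grid,
                 model.A_smc)
    dA = area_rate(model.A_med, model.a_rel, model.period, t_grid)
    R_v = inner_radius(A, model.R_ast)

    Q = (model.L - y)[:, None] * dA[None, :]          # um^3/s
    u_mean = Q / A[None, :]                           # um/s

    # pressure: dp/dy = -8 mu Q / (pi M); Q linear in y -> analytic integral
    mu = model.fluids.mu
    M_si = np.array([conductance_factor(rv, model.R_ast)
                     for rv in R_v]) * UM ** 4        # m^4
    coeff = -8.0 * mu * dA * UM ** 2 / (np.pi * M_si)  # Pa/m^2
    # p(y) = coeff * integral_0^y (L - y') dy'  (um^2 -> m^2)
    integ = (model.L * y - y ** 2 / 2.0) * UM ** 2     # m^2
    p = integ[:, None] * coeff[None, :]

    shape = np.array([peak_shape_factor(rv, model.R_ast) for rv in R_v])
    u_peak = float(np.max(np.abs(u_mean[0, :]) * shape))

    return FlowSolution(y=y, t=t_grid, u_mean=u_mean, p=p, A=A, dA_dt=dA,
                        R_v=R_v, u_peak=u_peak, model=model)


def peak_velocity(sol: FlowSolution) -> float:
    """Max over (r, y, t) of |axial velocity| (um/s); attained at y = 0."""
    return sol.u_peak


def analytic_peak_velocity(model: PVSModel, n_t: int = 401) -> float:
    """u_peak without building the full solution (used for calibration)."""
    t = np.linspace(0.0, model.period, n_t)
    A = area_law(model.A_med, model.a_rel, model.period, t, model.A_smc)
    dA = area_rate(model.A_med, model.a_rel, model.period, t)
    R_v = inner_radius(A, model.R_ast)
    u0 = model.L * dA / A
    shape = np.array([peak_shape_factor(rv, model.R_ast) for rv in R_v])
    return float(np.max(np.abs(u0) * shape))


def pressure_drop(sol: FlowSolution) -> tuple[float, float]:
    """(max over t of |p(L) - p(0)| in Pa, gradient in Pa/mm)."""
    dp = float(np.max(np.abs(sol.p[-1, :] - sol.p[0, :])))
    return dp, dp / (sol.model.L / 1000.0)


def mass_conservation_residual(sol: FlowSolution) -> float:
    """Max relative residual of dA/dt + d(A u_mean)/dy over the grid.

    Q = A u_mean is linear in y, so central differences are exact and the
    residual measures only arithmetic consistency of the stored fields.
    """
    Q = sol.A[None, :] * sol.u_mean
    dQ_dy = np.gradient(Q, sol.y, axis=0)
    resid = sol.dA_dt[None, :] + dQ_dy
    scale = np.max(np.abs(sol.dA_dt))
    if scale == 0:
        return float(np.max(np.abs(resid)))
    return float(np.max(np.abs(resid)) / scale)


def dimensionless_numbers(h_um: float, f_hz: float, u_um_s: float,
                          fluids: FluidConstants = FluidConstants()
                          ) -> tuple[float, float]:
    """Womersley Wo = h sqrt(2 rho pi f / mu) and Reynolds Re = rho u h / mu.

    ``h_um`` is the PVS gap thickness (um), ``f_hz`` the oscillation
    frequency, ``u_um_s`` the fluid velocity scale.  Evaluated in SI,
    returned dimensionless.
    """
    if h_um <= 0:
        raise ValueError("gap thickness must be positive")
    if f_hz < 0 or u_um_s < 0:
        raise ValueError("f and u must be >= 0")
    h = h_um * UM
    u = u_um_s * UM
    wo = h * np.sqrt(2 * fluids.rho * np.pi * f_hz / fluids.mu)
    re = fluids.rho * u * h / fluids.mu
    return float(wo), float(re)
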