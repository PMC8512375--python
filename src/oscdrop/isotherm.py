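"""Multicomponent ionic-surfactant adsorption and surface-tension isotherms.

A quasi-two-dimensional electrolyte model of mixed surfactant adsorption:
each adsorbing species i (e.g. a cationic monomer and a highly
surface-active heterodimer) obeys a mixed Frumkin isotherm evaluated at the
*subsurface* concentration, which differs from the bulk one by a Boltzmann
factor in the electric surface potential psi_s; the surface charge carried
by the adsorbed ions is balanced by a Gouy-Chapman diffuse layer. In
symbols, with theta_i the fractional coverages:

    subsurface:   c_i^s = c_i * exp(-z_i * F * psi_s / (R*T))
    isotherm:     b_i c_i^s = theta_i / (1 - sum_j theta_j)
                              * exp(-2 * sum_j a_ij * theta_j)
    eq. of state: Pi = -(R*T/omega_ref) * [ln(1 - sum theta)
                              + sum_ij a_ij theta_i theta_j] + Pi_el
    closure:      F * sum_i z_i theta_i / omega_ref
                      = sqrt(8 eps_w eps_0 R T I) * sinh(F psi_s / (2RT))
    Pi_el = (8 R T I / kappa) * [cosh(F psi_s / (2RT)) - 1]

where b_i (m^3/mol) is the surface activity, omega_ref (m^2/mol) the
reference molar area, a_ij the Frumkin lateral-interaction matrix (a > 0 =
attraction), I the ionic strength and kappa the inverse Debye length. The
surface tension is sigma = sigma0 - Pi, clamped at its CMC value above the
critical micelle concentration (micellar equilibria are not modelled).

Switching off charges, interactions and the second component reduces the
model exactly to the Langmuir isotherm and the Szyszkowski equation
sigma0 - sigma = (RT/omega) ln(1 + b c), which the tests use as closed-form
oracles.

Concentrations are mol/dm^3 at every public interface and converted to SI
internally. The equilibrium solver is deterministic (bracketed root find in
psi_s around a damped fixed point in theta, with concentration continuation
available through the curve evaluator).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares, root
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConvergenceError, InsufficientDataError, OscdropError

R_GAS = 8.314462618  # J/(mol K)
FARADAY = 96485.33212  # C/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
WATER_REL_PERMITTIVITY = 78.5  # ~295 K


@dataclass(frozen=True)
class SurfactantComponent:
    """One adsorbing species of the mixture.

    ``surface_activity`` b is in m^3/mol, ``molar_area`` omega in m^2/mol,
    ``charge`` z in elementary units; ``interaction`` is this component's
    row of the Frumkin matrix a_ij (padded with zeros to the number of
    components).
    """

    name: str
    charge: int
    surface_activity: float
    molar_area: float
    interaction: tuple = ()

    def __post_init__(self) -> None:
        if self.surface_activity < 0:
            raise ValueError(f"{self.name}: surface_activity must be >= 0")
        if self.molar_area <= 0:
            raise ValueError(f"{self.name}: molar_area must be > 0")
        if abs(self.charge) > 2:
            raise ValueError(f"{self.name}: |charge| must be <= 2")


@dataclass
class MixtureSystem:
    """A surfactant mixture: major monomer + minority dimer-forming species.

    ``minority_fraction`` f is the molar fraction of total surfactant
    present as the second component (the heterodimer), assumed fully
    dimerised; ``salt_mM`` is added 1:1 salt; ``counterion_charge`` the
    charge of the surfactant's own counterion. ``cmc_mM``, when set, clamps
    the tension isotherm above the critical micelle concentration.
    """

    components: list[SurfactantComponent]
    minority_fraction: float = 0.0
    salt_mM: float = 0.0
    counterion_charge: int = -1
    temperature: float = 295.0
    solvent_tension: float = 72.5  # mN/m
    cmc_mM: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.minority_fraction < 1.0:
            raise ValueError("minority_fraction must be in [0, 1)")
        if self.salt_mM < 0:
            raise ValueError("salt_mM must be >= 0")
        if not 20.0 < self.solvent_tension < 80.0:
            raise ValueError("solvent_tension must be in (20, 80) mN/m")
        if len(self.components) > 2 and self.minority_fraction > 0:
            raise ValueError("minority_fraction splits exactly two components")

    def interaction_matrix(self) -> np.ndarray:
        n = len(self.components)
        a = np.zeros((n, n))
        for i, comp in enumerate(self.components):
            row = np.asarray(comp.interaction, dtype=float)
            a[i, : row.size] = row[:n]
        return a

    @property
    def omega_ref(self) -> float:
        """Reference molar area of the equation of state (the first, major
        component's)."""
        return self.components[0].molar_area

    def copy(self) -> "MixtureSystem":
        return copy.deepcopy(self)


@dataclass
class Speciation:
    """Bulk composition at one total surfactant concentration (mol/dm^3)."""

    component_concentrations: dict[str, float]
    ion_concentrations: list[tuple[str, int, float]]  # (label, charge, conc)
    ionic_strength: float  # mol/dm^3

    @property
    def charge_balance(self) -> float:
        return sum(z * c for _, z, c in self.ion_concentrations)


@dataclass
class SurfaceState:
    """Adsorbed-layer state: coverages, surface potential, surface pressure."""

    coverages: dict[str, float]
    surface_potential: float  # V
    surface_pressure: float  # mN/m
    residual: float = 0.0

    @property
    def total_coverage(self) -> float:
        return sum(self.coverages.values())


def bulk_speciation(system: MixtureSystem, c_total: float) -> Speciation:
    """Split total surfactant into monomer/dimer and list all bulk ions.

    With minority fraction f, the dimer concentration is f*c_total and the
    monomer (1 - f)*c_total (the minority species is assumed fully
    dimerised). Counterions are added to enforce bulk electroneutrality;
    salt contributes a 1:1 ion pair. Ionic strength is (1/2) sum z^2 c over
    every ion.
    """
    if c_total < 0:
        raise ValueError("c_total must be >= 0")
    f = system.minority_fraction
    comps = system.components
    if len(comps) >= 2 and f > 0:
        concs = {comps[0].name: (1.0 - f) * c_total, comps[1].name: f * c_total}
    else:
        concs = {comps[0].name: c_total}
        for extra in comps[1:]:
            concs[extra.name] = 0.0

    ions: list[tuple[str, int, float]] = []
    net = 0.0
    for comp in comps:
        c = concs.get(comp.name, 0.0)
        if comp.charge != 0 and c > 0:
            ions.append((comp.name, comp.charge, c))
        net += comp.charge * c
    zc = system.counterion_charge
    if net != 0.0:
        if zc == 0 or np.sign(zc) == np.sign(net):
            raise ValueError("counterion_charge cannot balance the surfactant charge")
        ions.append(("counterion", zc, -net / zc))
    salt = system.salt_mM / 1000.0
    if salt > 0:
        ions.append(("salt+", +1, salt))
        ions.append(("salt-", -1, salt))
    ionic_strength = 0.5 * sum(z * z * c for _, z, c in ions)
    return Speciation(concs, ions, ionic_strength)


def _solve_coverages(x0: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Solve the mixed Frumkin system theta_i = x_i / (1 + sum x), with
    x_i = x0_i * exp(2 sum_j a_ij theta_j), by damped fixed point with a
    Newton (hybr) fallback."""
    theta = x0 / (1.0 + x0.sum())  # Langmuir start (exact for a = 0)
    if not a.any():
        return theta
    # full steps first (fast for contractive maps), damped retry if needed
    for lam, max_iter in ((1.0, 300), (0.5, 1500)):
        th = theta
        for _ in range(max_iter):
            x = x0 * np.exp(2.0 * (a @ th))
            new = x / (1.0 + x.sum())
            delta = np.max(np.abs(new - th))
            th = th + lam * (new - th)
            if delta < 1e-15:
                return th
            if not np.all(np.isfinite(th)):
                break

    def resid(th):
        x = x0 * np.exp(2.0 * (a @ th))
        return th - x / (1.0 + x.sum())

    sol = root(resid, theta, method="hybr", tol=1e-14)
    if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-10:
        raise ConvergenceError(
            "Frumkin coverage iteration did not converge",
            residual=float(np.max(np.abs(resid(sol.x)))),
        )
    return np.asarray(sol.x)


def equilibrium_coverage(system: MixtureSystem, bulk: Speciation) -> SurfaceState:
    """Solve for the adsorbed layer {theta_i, psi_s} at given bulk state.

    The surface potential is found by a bracketed root search on the
    Gouy-Chapman charge balance; at each candidate psi_s the coverages
    solve the mixed Frumkin system at the Boltzmann-corrected subsurface
    concentrations. Zero concentration returns the clean interface.
    """
    comps = system.components
    names = [c.name for c in comps]
    c_bulk = 1000.0 * np.array([bulk.component_concentrations.get(nm, 0.0) for nm in names])
    if not np.any(c_bulk > 0):
        return SurfaceState({nm: 0.0 for nm in names}, 0.0, 0.0)

    rt = R_GAS * system.temperature
    z = np.array([c.charge for c in comps], dtype=float)
    b = np.array([c.surface_activity for c in comps])
    a = system.interaction_matrix()
    omega = system.omega_ref
    i_si = 1000.0 * bulk.ionic_strength  # mol/m^3
    charged = np.any((z != 0) & (c_bulk > 0)) and i_si > 0

    def coverages(psi: float) -> np.ndarray:
        x0 = b * c_bulk * np.exp(-z * FARADAY * psi / rt)
        return _solve_coverages(x0, a)

    if not charged:
        psi_s = 0.0
        theta = coverages(0.0)
    else:
        gc_coef = np.sqrt(8.0 * WATER_REL_PERMITTIVITY * VACUUM_PERMITTIVITY * rt * i_si)

        def balance(psi: float) -> float:
            th = coverages(psi)
            return FARADAY * float(z @ th) / omega - gc_coef * np.sinh(
                FARADAY * psi / (2.0 * rt)
            )

        g0 = balance(0.0)
        if g0 == 0.0:
            psi_s = 0.0
        else:
            sign = np.sign(g0)
            hi = 0.05 * sign
            for _ in range(12):
                if balance(hi) * g0 < 0:
                    break
                hi *= 2.0
            else:
                raise ConvergenceError("could not bracket the surface potential")
            psi_s = brentq(balance, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
        theta = coverages(psi_s)

    total = float(theta.sum())
    if total >= 1.0:
        raise ConvergenceError("total coverage reached 1; unphysical parameters")
    pi_surf = -(rt / omega) * (np.log(1.0 - total) + float(theta @ a @ theta))
    pi_el = 0.0
    if charged and psi_s != 0.0:
        kappa = np.sqrt(
            2.0 * FARADAY**2 * i_si / (WATER_REL_PERMITTIVITY * VACUUM_PERMITTIVITY * rt)
        )
        pi_el = (8.0 * rt * i_si / kappa) * (np.cosh(FARADAY * psi_s / (2.0 * rt)) - 1.0)
    # residual of the isotherm equations at the solution
    x0 = b * c_bulk * np.exp(-z * FARADAY * psi_s / rt)
    x = x0 * np.exp(2.0 * (a @ theta))
    residual = float(np.max(np.abs(theta - x / (1.0 + x.sum()))))
    return SurfaceState(
        coverages=dict(zip(names, (float(v) for v in theta))),
        surface_potential=float(psi_s),
        surface_pressure=float((pi_surf + pi_el) * 1000.0),  # N/m -> mN/m
        residual=residual,
    )


def surface_tension(system: MixtureSystem, c_total: float) -> float:
    """Equilibrium surface tension (mN/m) at total concentration (mol/dm^3).

    sigma = sigma0 - Pi below the CMC; above a configured ``cmc_mM`` the
    flat micellar branch sigma(CMC) is returned.
    """
    if c_total < 0:
        raise ValueError("c_total must be >= 0")
    if c_total == 0.0:
        return system.solvent_tension
    if system.cmc_mM is not None and c_total > system.cmc_mM / 1000.0:
        c_total = system.cmc_mM / 1000.0
    state = equilibrium_coverage(system, bulk_speciation(system, c_total))
    return system.solvent_tension - state.surface_pressure


def surface_tension_curve(system: MixtureSystem, concentrations) -> np.ndarray:
    """Vectorised :func:`surface_tension` over a concentration grid."""
    return np.array([surface_tension(system, float(c)) for c in np.asarray(concentrations)])


@dataclass
class IsothermDataset:
    """(concentration, tension) pairs at one salt condition.

    Concentrations in mol/dm^3, strictly increasing; tensions in mN/m
    within (15, 80). ``cmc``/``tension_at_cmc`` are filled by
    :func:`detect_cmc`.
    """

    concentrations: np.ndarray
    tensions: np.ndarray
    salt_mM: float = 0.0
    meta: dict = field(default_factory=dict)
    cmc: float | None = None
    tension_at_cmc: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.tensions = np.asarray(self.tensions, dtype=float)
        if self.concentrations.size != self.tensions.size:
            raise ValueError("concentrations and tensions must have equal length")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.tensions <= 15.0) | (self.tensions >= 80.0)):
            raise ValueError("tensions must lie within (15, 80) mN/m")

    def __len__(self) -> int:
        return self.concentrations.size


# ---------------------------------------------------------------------------
# fitting


def _get_param(system: MixtureSystem, name: str) -> float:
    kind, *rest = name.split(":")
    if kind == "f":
        return system.minority_fraction
    idx = {c.name: i for i, c in enumerate(system.components)}
    comp = system.components[idx[rest[0]]]
    if kind == "b":
        return comp.surface_activity
    if kind == "omega":
        return comp.molar_area
    if kind == "a":
        j = idx[rest[1]]
        row = np.zeros(len(system.components))
        arr = np.asarray(comp.interaction, dtype=float)
        row[: arr.size] = arr
        return float(row[j])
    raise ValueError(f"unknown free parameter {name!r}")


def _set_param(system: MixtureSystem, name: str, value: float) -> None:
    kind, *rest = name.split(":")
    if kind == "f":
        system.minority_fraction = float(value)
        return
    idx = {c.name: i for i, c in enumerate(system.components)}
    i = idx[rest[0]]
    comp = system.components[i]
    if kind == "b":
        system.components[i] = replace(comp, surface_activity=float(value))
    elif kind == "omega":
        system.components[i] = replace(comp, molar_area=float(value))
    elif kind == "a":
        j = idx[rest[1]]
        row = np.zeros(len(system.components))
        arr = np.asarray(comp.interaction, dtype=float)
        row[: arr.size] = arr
        row[j] = float(value)
        system.components[i] = replace(comp, interaction=tuple(row))
        # keep the matrix symmetric
        other = system.components[j]
        orow = np.zeros(len(system.components))
        oarr = np.asarray(other.interaction, dtype=float)
        orow[: oarr.size] = oarr
        orow[i] = float(value)
        system.components[j] = replace(other, interaction=tuple(orow))
    else:
        raise ValueError(f"unknown free parameter {name!r}")


class MixedIsothermModel(RegressorMixin, BaseEstimator):
    """Fit the mixture adsorption model to a surface-tension isotherm.

    Free parameters are named ``"b:<component>"``, ``"omega:<component>"``,
    ``"a:<comp_i>:<comp_j>"`` or ``"f"`` (the minority molar fraction);
    b and omega are optimised in log10 space with multiplicative
    multi-start. Residuals are tension residuals (mN/m) at the data's
    concentrations (i.e. least squares on the usual sigma-vs-log-c axes).

    Attributes
    ----------
    system_ : MixtureSystem
        Template with the fitted parameter values substituted.
    residuals_ : ndarray
        sigma_model - sigma_data at the fitted optimum, mN/m.
    residual_rms_ : float
    cond_ : float
        Condition number of J^T J at the optimum; large values signal an
        under-determined parameter set (also raised as a warning).
    """

    def __init__(
        self,
        system: MixtureSystem,
        free_params: tuple = (),
        multistart: bool = True,
    ):
        self.system = system
        self.free_params = free_params
        self.multistart = multistart

    def _pack(self, values: np.ndarray) -> MixtureSystem:
        sys_ = self.system.copy()
        for name, v in zip(self.free_params, values):
            kind = name.split(":")[0]
            _set_param(sys_, name, 10.0**v if kind in ("b", "omega") else v)
        return sys_

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        sigma = np.asarray(y, dtype=float).ravel()
        if conc.size != sigma.size:
            raise ValueError("X and y must have equal length")
        cmc = self.system.cmc_mM
        below = conc if cmc is None else conc[conc <= cmc / 1000.0]
        if below.size < 5:
            raise InsufficientDataError(
                f"isotherm fit needs >= 5 points below the CMC, got {below.size}"
            )
        free = tuple(self.free_params)
        if not free:
            self.system_ = self.system.copy()
            self.residuals_ = surface_tension_curve(self.system_, conc) - sigma
            self.residual_rms_ = float(np.sqrt(np.mean(self.residuals_**2)))
            self.cond_ = 0.0
            return self

        x0, lb, ub = [], [], []
        for name in free:
            v = _get_param(self.system, name)
            kind = name.split(":")[0]
            if kind in ("b", "omega"):
                x0.append(np.log10(v) if v > 0 else 0.0)
                lb.append(x0[-1] - 4.0)
                ub.append(x0[-1] + 4.0)
            elif kind == "f":
                x0.append(v)
                lb.append(0.0)
                ub.append(0.999)
            else:  # interaction
                x0.append(v)
                lb.append(-5.0)
                ub.append(5.0)
        x0, lb, ub = np.array(x0), np.array(lb), np.array(ub)

        def residuals(xv):
            return surface_tension_curve(self._pack(xv), conc) - sigma

        starts = [x0]
        if self.multistart:
            log_shift = np.array(
                [np.log10(4.0) if n.split(":")[0] in ("b", "omega") else 0.0 for n in free]
            )
            starts += [np.clip(x0 + log_shift, lb, ub), np.clip(x0 - log_shift, lb, ub)]
        best = None
        for s in starts:
            try:
                sol = least_squares(
                    residuals, s, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except (ConvergenceError, OscdropError):
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise ConvergenceError("isotherm fit did not converge from any start")

        self.system_ = self._pack(best.x)
        self.residuals_ = best.fun
        self.residual_rms_ = float(np.sqrt(np.mean(best.fun**2)))
        JTJ = best.jac.T @ best.jac
        self.cond_ = float(np.linalg.cond(JTJ))
        if len(free) > 1 and self.cond_ > 1e10:
            warnings.warn(
                f"isotherm fit is nearly under-determined "
                f"(covariance condition number {self.cond_:.2e})",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        sys_ = getattr(self, "system_", self.system)
        return surface_tension_curve(sys_, np.asarray(X, dtype=float).ravel())


def fit_isotherm(
    data: IsothermDataset,
    system_template: MixtureSystem,
    free_params=(),
    multistart: bool = True,
) -> tuple[MixtureSystem, np.ndarray]:
    """Fit free parameters of the mixture model to an isotherm dataset.

    Thin wrapper over :class:`MixedIsothermModel`; the template's
    ``salt_mM`` is overridden by the dataset's. Returns the fitted system
    and the tension residuals.
    """
    template = system_template.copy()
    template.salt_mM = data.salt_mM
    model = MixedIsothermModel(template, tuple(free_params), multistart=multistart)
    model.fit(data.concentrations, data.tensions)
    return model.system_, model.residuals_


# ---------------------------------------------------------------------------
# CMC detection


class CMCBreakpoint(BaseEstimator):
    """Two-segment breakpoint fit of sigma vs log10(c) locating the CMC.

    Straight lines are fitted below and above every admissible split
    (``min_points`` = 4 per side); the split minimising the total squared
    residual wins and the CMC is the lines' intersection.

    Attributes
    ----------
    cmc_ : float
        Intersection abscissa, mol/dm^3.
    tension_at_cmc_ : float
        Intersection ordinate, mN/m.
    slopes_ : tuple
        (below, above) slopes in mN/m per decade.
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        sigma = np.asarray(y, dtype=float).ravel()
        n = conc.size
        m = self.min_points
        if n < 2 * m:
            raise InsufficientDataError(
                f"CMC detection needs >= {m} points on each side of the break "
                f"({2 * m} total), got {n}"
            )
        x = np.log10(conc)
        best = None
        for split in range(m, n - m + 1):
            p1, r1 = _linefit(x[:split], sigma[:split])
            p2, r2 = _linefit(x[split:], sigma[split:])
            if abs(p1[0] - p2[0]) < 1e-12:
                continue  # parallel: no intersection
            xc = (p2[1] - p1[1]) / (p1[0] - p2[0])
            if not (x[0] <= xc <= x[-1]):
                continue
            sse = r1 + r2
            if best is None or sse < best[0]:
                best = (sse, p1, p2, xc)
        if best is None:
            raise OscdropError(
                "no admissible breakpoint: the isotherm slope is monotone "
                "(no CMC within the measured range)"
            )
        _, p1, p2, xc = best
        self.cmc_ = float(10.0**xc)
        self.tension_at_cmc_ = float(p1[0] * xc + p1[1])
        self.slopes_ = (float(p1[0]), float(p2[0]))
        return self


def _linefit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    p, res, *_ = np.polyfit(x, y, 1, full=True)
    sse = float(res[0]) if res.size else 0.0
    return p, sse


def detect_cmc(data: IsothermDataset, min_points: int = 4) -> tuple[float, float]:
    """Locate the CMC of an isotherm dataset; fills ``data.cmc`` in place.

    Returns ``(cmc, tension_at_cmc)`` in (mol/dm^3, mN/m).
    """
    det = CMCBreakpoint(min_points=min_points).fit(data.concentrations, data.tensions)
    data.cmc = det.cmc_
    data.tension_at_cmc = det.tension_at_cmc_
    return det.cmc_, det.tension_at_cmc_
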