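"""Lucassen-van den Tempel (LvdT) diffusional surface viscoelasticity.

For a soluble surfactant monolayer whose exchange with the bulk is
diffusion-controlled, the complex dilational modulus at oscillation
frequency ``nu`` is

    eps(nu) = eps0 * (1 + xi + i*xi) / (1 + 2*xi + 2*xi**2),
    xi = sqrt(nu_D / (2*nu)),

where ``eps0`` is the Gibbs elasticity (the insoluble-monolayer,
high-frequency limit, mN/m) and ``nu_D`` the characteristic frequency of
diffusional transport (Hz). Both parts are non-negative; ``eps_r -> eps0``
and ``eps_i -> 0`` as ``nu -> inf``, both vanish as ``nu -> 0``, and within
the model ``0 < eps_i < eps_r < eps0`` whenever ``xi > 0`` — a measured
loss part exceeding the storage part therefore signals physics beyond
diffusional exchange (micellar relaxation, mixed layers).

:class:`LvdTModel` fits (eps0, nu_D) to a measured modulus spectrum as a
scikit-learn style regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConvergenceError, InsufficientDataError
from .modulus import ModulusSpectrum


@dataclass(frozen=True)
class LvdTParams:
    """Gibbs elasticity eps0 (mN/m) and diffusion frequency nu_D (Hz)."""

    gibbs_elasticity: float
    diffusion_frequency: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gibbs_elasticity) and self.gibbs_elasticity >= 0):
            raise ValueError("gibbs_elasticity must be finite and >= 0")
        if not (np.isfinite(self.diffusion_frequency) and self.diffusion_frequency >= 0):
            raise ValueError("diffusion_frequency must be finite and >= 0")


def lvdt_modulus(params: LvdTParams, frequency) -> np.ndarray | complex:
    """Evaluate the LvdT complex modulus at one or more frequencies (Hz)."""
    freq = np.asarray(frequency, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be positive")
    xi = np.sqrt(params.diffusion_frequency / (2.0 * freq))
    denom = 1.0 + 2.0 * xi + 2.0 * xi**2
    eps = params.gibbs_elasticity * ((1.0 + xi) + 1j * xi) / denom
    if np.isscalar(frequency):
        return complex(eps)
    return eps


@dataclass
class LvdTFit:
    """Converged LvdT fit result (see :class:`LvdTModel` for the machinery)."""

    params: LvdTParams
    param_uncertainty: tuple[float, float]  # 1-sigma (eps0, nu_D)
    residual_rms: float
    n_points: int
    converged: bool


#: default multi-start grid: eps0 (mN/m) x nu_D (Hz)
DEFAULT_STARTS_EPS0 = (5.0, 20.0, 80.0)
DEFAULT_STARTS_NUD = (1e-4, 1e-2, 1.0)
#: optimisation bounds
EPS0_BOUNDS = (1e-12, 500.0)
NUD_BOUNDS = (0.0, 10.0)


class LvdTModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of the LvdT modulus to a frequency sweep.

    Parameters
    ----------
    part : {"real", "complex"}
        ``"real"`` (default) fits the storage modulus eps_r(nu) only —
        the appropriate choice when the loss part is contaminated by
        non-diffusional relaxation. ``"complex"`` fits both parts jointly;
        ``y`` must then be complex.
    starts_eps0, starts_nud : tuple of float
        Multi-start grid; every pairwise combination is tried and the best
        converged optimum kept.
    weights : array or None
        Optional per-point weights (1/sigma); default unweighted.

    Attributes
    ----------
    eps0_ : float
        Fitted Gibbs elasticity, mN/m.
    nu_d_ : float
        Fitted diffusion frequency, Hz.
    eps0_sd_, nu_d_sd_ : float
        1-sigma uncertainties from the linearised covariance at the optimum.
    residual_rms_ : float
        Root-mean-square residual, mN/m.
    n_points_ : int
        Number of frequencies fitted.
    converged_ : bool
        True when at least one start converged.

    Examples
    --------
    >>> import numpy as np
    >>> from oscdrop.lvdt import LvdTModel, LvdTParams, lvdt_modulus
    >>> nu = np.logspace(np.log10(0.005), np.log10(0.2), 15)
    >>> y = lvdt_modulus(LvdTParams(30.1, 0.0032), nu).real
    >>> fit = LvdTModel().fit(nu, y)
    >>> round(fit.eps0_, 3), round(fit.nu_d_, 6)
    (30.1, 0.0032)
    """

    def __init__(
        self,
        part: str = "real",
        starts_eps0: tuple = DEFAULT_STARTS_EPS0,
        starts_nud: tuple = DEFAULT_STARTS_NUD,
        weights=None,
    ):
        self.part = part
        self.starts_eps0 = starts_eps0
        self.starts_nud = starts_nud
        self.weights = weights

    def _residuals(self, theta, freq, y, w):
        eps = lvdt_modulus(LvdTParams(theta[0], theta[1]), freq)
        if self.part == "real":
            r = eps.real - y
        else:
            r = np.concatenate([(eps.real - y.real), (eps.imag - y.imag)])
            w = None if w is None else np.concatenate([w, w])
        return r if w is None else r * w

    def fit(self, X, y):
        """Fit (eps0, nu_D) to frequencies ``X`` (Hz) and moduli ``y`` (mN/m)."""
        if self.part not in ("real", "complex"):
            raise ValueError(f"part must be 'real' or 'complex', got {self.part!r}")
        freq = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=complex if self.part == "complex" else float).ravel()
        if freq.size != y.size:
            raise ValueError("X and y must have the same length")
        if np.unique(freq).size < 3:
            raise InsufficientDataError(
                f"LvdT fit needs >= 3 distinct frequencies, got {np.unique(freq).size}"
            )
        w = None if self.weights is None else np.asarray(self.weights, dtype=float)

        lb = (EPS0_BOUNDS[0], NUD_BOUNDS[0])
        ub = (EPS0_BOUNDS[1], NUD_BOUNDS[1])
        best = None
        best_bad = None  # best non-converged attempt, for the failure report
        for e0 in self.starts_eps0:
            for nd in self.starts_nud:
                try:
                    sol = least_squares(
                        self._residuals,
                        x0=(e0, nd),
                        bounds=(lb, ub),
                        args=(freq, y, w),
                        xtol=1e-15,
                        ftol=1e-15,
                        gtol=1e-15,
                    )
                except Exception:
                    continue
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
                elif not sol.success and (best_bad is None or sol.cost < best_bad.cost):
                    best_bad = sol
        if best is None:
            resid = None if best_bad is None else float(np.sqrt(2 * best_bad.cost))
            raise ConvergenceError("no LvdT fit start converged", residual=resid)

        self.eps0_, self.nu_d_ = (float(v) for v in best.x)
        self.n_points_ = int(freq.size)
        n_resid = best.fun.size
        self.residual_rms_ = float(np.sqrt(np.mean(best.fun**2)))
        # linearised covariance: sigma^2 * (J^T J)^-1
        dof = max(n_resid - 2, 1)
        s2 = 2.0 * best.cost / dof
        JTJ = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(JTJ)
            self.eps0_sd_ = float(np.sqrt(max(cov[0, 0], 0.0)))
            self.nu_d_sd_ = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            self.eps0_sd_ = self.nu_d_sd_ = float("nan")
        self.converged_ = True
        return self

    def predict(self, X):
        """Model eps_r (part='real') or complex eps at frequencies ``X``."""
        freq = np.asarray(X, dtype=float).ravel()
        eps = lvdt_modulus(LvdTParams(self.eps0_, self.nu_d_), freq)
        return eps.real if self.part == "real" else eps

    @property
    def params_(self) -> LvdTParams:
        return LvdTParams(self.eps0_, self.nu_d_)


def fit_lvdt(
    spectrum: ModulusSpectrum | tuple,
    part: str = "real",
    starts_eps0: tuple = DEFAULT_STARTS_EPS0,
    starts_nud: tuple = DEFAULT_STARTS_NUD,
    weights=None,
) -> LvdTFit:
    """Fit the LvdT model to a modulus spectrum (thin wrapper over LvdTModel).

    Accepts a :class:`ModulusSpectrum` or a ``(frequencies, moduli)`` pair;
    ``part="real"`` uses the storage part only, ``part="complex"`` fits
    eps_r and eps_i jointly.
    """
    if isinstance(spectrum, ModulusSpectrum):
        freq = spectrum.frequencies
        y = spectrum.eps_real if part == "real" else spectrum.eps_real + 1j * spectrum.eps_imag
    else:
        freq, y = spectrum
    model = LvdTModel(
        part=part, starts_eps0=starts_eps0, starts_nud=starts_nud, weights=weights
    ).fit(freq, y)
    return LvdTFit(
        params=model.params_,
        param_uncertainty=(model.eps0_sd_, model.nu_d_sd_),
        residual_rms=model.residual_rms_,
        n_points=model.n_points_,
        converged=model.converged_,
    )
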