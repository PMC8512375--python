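"""Locally weighted polynomial (Loess) smoothing.

Local regression with tricube weights, the smoother classically applied to
raw surface-tension traces before harmonic analysis. Implemented directly
(weighted least squares per evaluation point) because the analysis needs
local *quadratic* fits and evaluation on the trace's own, possibly
irregular, time grid. Endpoints are handled by one-sided windows: the
nearest-neighbour window simply becomes asymmetric near the edges.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess_smooth(
    signal: np.ndarray,
    t: np.ndarray,
    span_fraction: float = 0.1,
    degree: int = 2,
) -> np.ndarray:
    """Smooth ``signal(t)`` by tricube-weighted local polynomial regression.

    Parameters
    ----------
    signal, t : array
        Equal-length sample values and strictly increasing sample times.
    span_fraction : float
        Window size as a fraction of the number of points, in (0, 1]. The
        window must cover at least ``degree + 2`` points.
    degree : int
        Local polynomial degree (0 = moving weighted mean, 1 = linear,
        2 = quadratic, the default for oscillation traces).

    Returns
    -------
    array
        Smoothed signal, same length as the input. Exactly reproduces any
        polynomial of degree <= ``degree``.
    """
    signal = np.asarray(signal, dtype=float)
    t = np.asarray(t, dtype=float)
    if signal.shape != t.shape or signal.ndim != 1:
        raise ConfigurationError("signal and t must be equal-length 1-d arrays")
    n = signal.size
    if degree < 0:
        raise ConfigurationError("degree must be >= 0")
    if not 0.0 < span_fraction <= 1.0:
        raise ConfigurationError(f"span_fraction must be in (0, 1], got {span_fraction}")
    k = int(np.ceil(span_fraction * n))
    min_k = degree + 2
    if k < min_k:
        raise ConfigurationError(
            f"span_fraction {span_fraction} covers {k} points but degree "
            f"{degree} needs at least {min_k} (minimum span {min_k / n:.4f})"
        )

    dts = np.diff(t)
    uniform = np.allclose(dts, dts[0], rtol=1e-9, atol=0.0)
    out = np.empty(n)
    half = k // 2

    def point_fit(i: int) -> float:
        lo = min(max(i - half, 0), n - k)
        tw = t[lo : lo + k]
        yw = signal[lo : lo + k]
        # local coordinate scaled by max in-window distance for tricube
        dt = tw - t[i]
        dmax = np.max(np.abs(dt))
        if dmax == 0.0:
            return float(yw.mean())
        w = _tricube(dt / (dmax * (1.0 + 1e-12)))
        sw = np.sqrt(w)
        X = np.vander(dt / dmax, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
        return float(coef[0])  # local fit evaluated at dt = 0

    if uniform and n >= k:
        # On a uniform grid every full (interior) window shares the same
        # offsets and weights, so the local fit reduces to one fixed
        # equivalent kernel applied by convolution; only the edge points
        # with one-sided windows need individual fits.
        offsets = (np.arange(k) - half) * dts[0]
        dmax = np.max(np.abs(offsets))
        w = _tricube(offsets / (dmax * (1.0 + 1e-12)))
        X = np.vander(offsets / dmax, degree + 1, increasing=True)
        XtW = X.T * w
        kernel = np.linalg.solve(XtW @ X, XtW)[0]  # row evaluating at 0
        smoothed_interior = np.correlate(signal, kernel, mode="valid")
        out[half : half + smoothed_interior.size] = smoothed_interior
        for i in range(half):
            out[i] = point_fit(i)
        for i in range(half + smoothed_interior.size, n):
            out[i] = point_fit(i)
    else:
        for i in range(n):
            out[i] = point_fit(i)
    return out
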