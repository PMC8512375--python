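"""Oscillating-drop trace container.

An :class:`OscillationTrace` holds one pendant-drop oscillation experiment:
the drop surface area ``A(t)`` (mm^2) imposed by the instrument and the
surface tension response ``sigma(t)`` (mN/m), sampled on a strictly
increasing time grid, at one nominal oscillation frequency ``nu`` (Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TraceError

#: minimum number of imposed-oscillation periods a trace must span
MIN_PERIODS = 3.0
#: minimum samples per period for the fundamental to be representable
MIN_SAMPLES_PER_PERIOD = 4.0


@dataclass
class OscillationTrace:
    """Time series of drop area and surface tension at one frequency.

    Parameters
    ----------
    t : array
        Sample times in seconds, strictly increasing.
    area : array
        Drop surface area in mm^2, positive.
    tension : array
        Surface tension in mN/m, positive.
    nominal_frequency : float
        Imposed oscillation frequency in Hz.
    meta : dict
        Free-form condition labels (concentration_mM, salt_mM, ...).
    """

    t: np.ndarray
    area: np.ndarray
    tension: np.ndarray
    nominal_frequency: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.tension = np.asarray(self.tension, dtype=float)
        self.validate()

    def validate(self) -> None:
        """Check the trace invariants, raising :class:`TraceError` on failure."""
        n = self.t.size
        if not (self.area.size == n and self.tension.size == n):
            raise TraceError(
                f"t, area, tension must have equal length; got "
                f"{n}, {self.area.size}, {self.tension.size}"
            )
        if n < 2:
            raise TraceError("trace needs at least 2 samples")
        dt = np.diff(self.t)
        if not np.all(dt > 0):
            bad = int(np.argmin(dt > 0))
            raise TraceError(f"time must be strictly increasing (sample {bad + 1})")
        if not np.all(self.area > 0):
            raise TraceError("area must be positive everywhere")
        if not np.all(self.tension > 0):
            raise TraceError("tension must be positive everywhere")
        nu = self.nominal_frequency
        if not (np.isfinite(nu) and nu > 0):
            raise TraceError(f"nominal_frequency must be positive, got {nu}")
        span = self.t[-1] - self.t[0]
        if span * nu < MIN_PERIODS:
            raise TraceError(
                f"trace spans {span * nu:.2f} periods at {nu} Hz; "
                f"at least {MIN_PERIODS:g} are required"
            )
        median_dt = float(np.median(dt))
        if median_dt * nu > 1.0 / MIN_SAMPLES_PER_PERIOD:
            raise TraceError(
                f"only {1.0 / (median_dt * nu):.2f} samples per period at "
                f"{nu} Hz; at least {MIN_SAMPLES_PER_PERIOD:g} are required"
            )

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def n_periods(self) -> float:
        """Number of fundamental periods spanned."""
        return self.duration * self.nominal_frequency

    def __len__(self) -> int:
        return self.t.size
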