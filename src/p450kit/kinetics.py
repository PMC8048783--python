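"""Turnover-number and coupling-efficiency analytics.

The turnover number (TON, umol substrate consumed per umol P450 per
minute) is evaluated over the contiguous time window with the highest
observed substrate consumption rate: a least-squares line is fitted to
every contiguous sample window spanning at least ``window_min`` minutes
and the steepest negative slope wins.  Coupling efficiency is the
percentage of consumed NADH reducing equivalents that ended up in
product rather than uncoupling pathways.  The Beer-Lambert helpers use
the standard molar absorption coefficients: 6.22 mM^-1 cm^-1 for NADH
at 340 nm, 19.1 mM^-1 cm^-1 for reduced cytochrome c, and 91 mM^-1 cm^-1
for the 450-490 nm CO-difference of reduced P450.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError

EPSILON_NADH_340_mM = 6.22  # mM^-1 cm^-1
EPSILON_CYTC_mM = 19.1  # mM^-1 cm^-1, reduced cytochrome c readout
EPSILON_CO_DIFF_mM = 91.0  # mM^-1 cm^-1, P450 CO-difference (450-490 nm)

DEFAULT_TON_WINDOW_MIN = 120.0


@dataclass(frozen=True)
class TimeCourse:
    """Concentration-vs-time record of one conversion reaction."""

    time: np.ndarray  # min, strictly increasing
    substrate: np.ndarray  # uM
    p450_total: float  # uM
    product: np.ndarray | None = None  # uM
    nadh_abs: np.ndarray | None = None  # AU at 340 nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "substrate", np.asarray(self.substrate, float))
        if self.time.shape != self.substrate.shape:
            raise ValueError("time and substrate must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.substrate < 0):
            raise DomainError("substrate concentrations must be >= 0")
        if self.p450_total <= 0:
            raise DomainError("p450_total must be positive")


@dataclass(frozen=True)
class KineticsResult:
    """TON and, when available, coupling figures for one reaction."""

    ton: float  # umol substrate / (umol P450 * min)
    window: tuple[float, float]  # (t_start, t_end), min
    coupling_percent: float | None = None
    nadh_consumed_uM: float | None = None
    substrate_converted_uM: float | None = None
    flags: tuple[str, ...] = ()


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y against t."""
    t = t - t.mean()
    return float(np.dot(t, y - y.mean()) / np.dot(t, t))


def ton_from_timecourse(
    tc: TimeCourse, window_min: float = DEFAULT_TON_WINDOW_MIN
) -> KineticsResult:
    """TON from the steepest substrate-consumption window.

    Scans every contiguous sample window spanning at least ``window_min``
    minutes, fits a least-squares line, and converts the steepest
    negative slope to a TON.  A best slope that is non-negative clamps
    the TON to zero and sets a ``no_consumption`` flag.
    """
    t, s = tc.time, tc.substrate
    n = len(t)
    if n < 3:
        raise InsufficientDataError("need at least 3 time points")
    best = np.inf
    best_window = (float(t[0]), float(t[-1]))
    found = False
    for i in range(n - 1):
        for j in range(i + 1, n):
            if t[j] - t[i] < window_min:
                continue
            sl = _slope(t[i : j + 1], s[i : j + 1])
            found = True
            if sl < best:
                best = sl
                best_window = (float(t[i]), float(t[j]))
    if not found:
        raise InsufficientDataError(
            f"no contiguous window spans {window_min} min"
        )
    flags: tuple[str, ...] = ()
    if best >= 0:
        ton = 0.0
        flags = ("no_consumption",)
    else:
        ton = -best / tc.p450_total
    return KineticsResult(ton=ton, window=best_window, flags=flags)


def coupling_efficiency(
    substrate_converted_uM: float, nadh_consumed_uM: float
) -> tuple[float, tuple[str, ...]]:
    """Coupling efficiency in percent, with plausibility flags.

    100 * substrate converted / NADH consumed; values above 100 % are
    stoichiometrically implausible and flagged, not rejected.
    """
    if nadh_consumed_uM <= 0:
        raise DomainError("NADH consumed must be positive")
    if substrate_converted_uM < 0:
        raise DomainError("substrate converted must be >= 0")
    pct = 100.0 * substrate_converted_uM / nadh_consumed_uM
    flags = ("over_stoichiometric",) if pct > 100.0 else ()
    return pct, flags


def nadh_consumed_from_abs(
    a0: float, a1: float, path_cm: float = 1.0
) -> tuple[float, tuple[str, ...]]:
    """NADH consumed (uM) from the drop in A340 via Beer-Lambert."""
    if path_cm <= 0:
        raise DomainError("path length must be positive")
    delta = a0 - a1
    flags: tuple[str, ...] = ()
    if delta < 0:
        flags = ("negative_consumption",)
    # epsilon in AU per uM per cm
    eps_per_uM = EPSILON_NADH_340_mM * 1e-3
    return delta / (eps_per_uM * path_cm), flags


def etc_activity(
    slope_A550_per_min: float,
    reaction_volume_mL: float,
    sample_volume_mL: float,
    path_cm: float = 1.0,
) -> float:
    """Electron-transfer-chain activity (U/mL of sample) from the
    cytochrome c reduction slope.

    The cuvette rate in mM/min follows from Beer-Lambert with
    epsilon = 19.1 mM^-1 cm^-1; scaling by reaction/sample volume gives
    umol min^-1 per mL of the enzyme sample (U/mL).
    """
    if slope_A550_per_min < 0:
        raise DomainError("slope must be >= 0")
    if reaction_volume_mL <= 0 or sample_volume_mL <= 0 or path_cm <= 0:
        raise DomainError("volumes and path length must be positive")
    rate_mM_per_min = slope_A550_per_min / (EPSILON_CYTC_mM * path_cm)
    # mM = umol/mL, so cuvette rate in umol/(mL*min); rescale to sample mL
    return rate_mM_per_min * reaction_volume_mL / sample_volume_mL


def p450_conc_from_co_difference(
    delta_A_450_490: float,
    path_cm: float = 1.0,
    epsilon_mM: float = EPSILON_CO_DIFF_mM,
) -> tuple[float, tuple[str, ...]]:
    """P450 concentration (uM) from a CO-difference spectrum amplitude."""
    if path_cm <= 0 or epsilon_mM <= 0:
        raise DomainError("path length and epsilon must be positive")
    flags: tuple[str, ...] = ()
    if delta_A_450_490 < 0:
        flags = ("negative_difference",)
    return delta_A_450_490 / (epsilon_mM * 1e-3 * path_cm), flags


def analyze_timecourse(
    tc: TimeCourse,
    window_min: float = DEFAULT_TON_WINDOW_MIN,
    nadh0_uM: float | None = None,
) -> KineticsResult:
    """TON plus coupling figures when the time course carries an NADH trace.

    ``nadh0_uM`` overrides the initial NADH amount; by default it is
    inferred from the first A340 reading.
    """
    base = ton_from_timecourse(tc, window_min=window_min)
    if tc.nadh_abs is None:
        return base
    a0 = float(tc.nadh_abs[0]) if nadh0_uM is None else nadh0_uM * EPSILON_NADH_340_mM * 1e-3
    consumed, nflags = nadh_consumed_from_abs(a0, float(tc.nadh_abs[-1]))
    converted = float(tc.substrate[0] - tc.substrate[-1])
    converted = max(converted, 0.0)
    if consumed <= 0:
        return KineticsResult(
            ton=base.ton, window=base.window, flags=base.flags + nflags
        )
    pct, cflags = coupling_efficiency(converted, consumed)
    return KineticsResult(
        ton=base.ton,
        window=base.window,
        coupling_percent=pct,
        nadh_consumed_uM=consumed,
        substrate_converted_uM=converted,
        flags=base.flags + nflags + cflags,
    )
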