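"""Type-I spin-shift titration analysis and tight-binding K_D fitting.

Substrate binding to a P450 displaces the sixth (water) ligand of the
heme iron, shifting the Soret band from ~420 nm (low spin) towards
~390 nm (high spin).  The peak-to-trough absorbance difference
dA = A(386) - A(420) grows with the bound-enzyme fraction, and because
the dissociation constants here are comparable to the enzyme
concentration, dA versus total ligand follows the quadratic
tight-binding (Morrison) equation rather than a simple hyperbola:

    dA(L) = dA_max * [ (E + L + K_D) - sqrt((E + L + K_D)^2 - 4 E L) ] / (2 E)

with E the total enzyme concentration.  Fitting works internally in uM
and reports K_D in nM.  When the profile likelihood of K_D is flat down
to zero (K_D far below E), only an upper limit is identifiable and the
fit is flagged ``upper_bound_only``; series with no measurable shift
are flagged ``no_shift``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from scipy.optimize import brentq

from .errors import (
    DegenerateBasisError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
)

#: chi-square increase bounding the 95 % profile-likelihood interval (1 dof)
_DCHI2_95 = 3.84

#: relative noise floor (fraction of dA_max) used when residuals are
#: essentially zero, so identifiability is judged against a realistic
#: instrument precision rather than floating-point noise
_SIGMA_FLOOR_REL = 0.005

#: absolute dA floor (AU) below which a series counts as "no shift"
DEFAULT_NOISE_FLOOR_AU = 0.005


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # AU

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, float))
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def at(self, nm: float) -> float:
        """Linearly interpolated absorbance at a wavelength."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= nm <= hi):
            raise DomainError(f"{nm} nm outside spectrum range [{lo}, {hi}]")
        return float(np.interp(nm, self.wavelengths, self.absorbance))


@dataclass(frozen=True)
class TitrationSeries:
    """dA versus total ligand at fixed total enzyme concentration."""

    ligand_total: np.ndarray  # uM
    delta_A: np.ndarray  # AU
    enzyme_total: float = 3.0  # uM

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_total", np.asarray(self.ligand_total, float))
        object.__setattr__(self, "delta_A", np.asarray(self.delta_A, float))
        if self.ligand_total.shape != self.delta_A.shape:
            raise ValueError("ligand_total and delta_A must have equal length")
        if np.any(self.ligand_total < 0):
            raise DomainError("ligand concentrations must be >= 0")
        if self.enzyme_total <= 0:
            raise DomainError("enzyme_total must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Result of a tight-binding fit.

    ``kd_nM`` is the best-fit dissociation constant; when
    ``status == "upper_bound_only"`` the identifiable quantity is
    ``kd_upper_nM``, the 95 % profile upper limit, conventionally
    reported as "< X nM".
    """

    kd_nM: float
    kd_se_nM: float
    delta_A_max: float
    delta_A_max_se: float
    status: str  # "ok" | "upper_bound_only" | "no_shift"
    kd_upper_nM: float | None = None
    chi2: float = 0.0
    n_points: int = 0

    def summary(self) -> str:
        if self.status == "no_shift":
            return "no spin shift observed"
        if self.status == "upper_bound_only":
            return f"K_D < {self.kd_upper_nM:.3g} nM"
        return f"K_D = {self.kd_nM:.3g} +/- {self.kd_se_nM:.2g} nM"


def difference_signal(
    spectrum: Spectrum, peak_nm: float = 386.0, trough_nm: float = 420.0
) -> float:
    """Peak-to-trough difference A(peak) - A(trough), interpolated."""
    return spectrum.at(peak_nm) - spectrum.at(trough_nm)


def tight_binding_model(
    L: np.ndarray | float, E: float, K_D: float, delta_A_max: float
) -> np.ndarray | float:
    """Quadratic tight-binding (Morrison) signal for total ligand L.

    All concentrations in the same unit (uM internally).  Exact at
    K_D = 0, where it reduces to the stoichiometric limit
    delta_A_max * min(L, E) / E.
    """
    if E <= 0:
        raise DomainError("enzyme concentration must be positive")
    if K_D < 0 or delta_A_max < 0:
        raise DomainError("K_D and delta_A_max must be >= 0")
    L_arr = np.asarray(L, dtype=float)
    if np.any(L_arr < 0):
        raise DomainError("ligand concentration must be >= 0")
    s = E + L_arr + K_D
    disc = np.clip(s * s - 4.0 * E * L_arr, 0.0, None)
    out = delta_A_max * (s - np.sqrt(disc)) / (2.0 * E)
    return out if np.ndim(L) else float(out)


def _average_replicates(
    series: TitrationSeries,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Average replicate points at identical L; return (L, y, sigma, sd0).

    ``sigma`` per averaged point comes from the replicate spread when at
    least two replicates exist anywhere (pooled SD), else ones.  ``sd0``
    is the replicate SD at L = 0 (NaN when unavailable).
    """
    L = series.ligand_total
    y = series.delta_A
    uniq = np.unique(L)
    means = np.array([y[L == u].mean() for u in uniq])
    sds = np.array([y[L == u].std(ddof=1) if (L == u).sum() > 1 else np.nan for u in uniq])
    sd0 = sds[uniq == 0.0][0] if 0.0 in uniq else np.nan
    if np.any(np.isfinite(sds)):
        pooled = np.nanmean(sds)
        sigma = np.where(np.isfinite(sds) & (sds > 0), sds, max(pooled, 1e-12))
    else:
        sigma = np.ones_like(means)
    return uniq, means, sigma, sd0


def fit_tight_binding(
    series: TitrationSeries,
    noise_floor: float | None = None,
) -> BindingFit:
    """Weighted least-squares fit of the quadratic tight-binding model.

    For each trial K_D the optimal amplitude has a closed form, so the
    fit profiles chi-square over K_D alone.  Status flags:

    - ``no_shift`` when max |dA| is below the noise floor (default: three
      times the replicate SD at L = 0 when replicates exist, else
      ``DEFAULT_NOISE_FLOOR_AU``);
    - ``upper_bound_only`` when the 95 % profile interval for K_D
      extends to zero, i.e. only "K_D < upper limit" is supported.
    """
    L, y, sigma, sd0 = _average_replicates(series)
    if len(L) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct ligand concentrations, got {len(L)}"
        )
    E = series.enzyme_total
    if noise_floor is None:
        noise_floor = 3.0 * sd0 if np.isfinite(sd0) and sd0 > 0 else DEFAULT_NOISE_FLOOR_AU
    if np.max(np.abs(y)) < noise_floor:
        return BindingFit(
            kd_nM=0.0, kd_se_nM=np.nan, delta_A_max=0.0, delta_A_max_se=np.nan,
            status="no_shift", n_points=len(L),
        )
    w = 1.0 / sigma**2

    def amp_and_chi2(kd: float) -> tuple[float, float]:
        m = tight_binding_model(L, E, kd, 1.0)
        denom = np.sum(w * m * m)
        if denom <= 0:
            return 0.0, float(np.sum(w * y * y))
        a = max(float(np.sum(w * y * m) / denom), 0.0)
        r = y - a * m
        return a, float(np.sum(w * r * r))

    def chi2(kd: float) -> float:
        return amp_and_chi2(kd)[1]

    # coarse log-spaced bracket, then local refinement
    kd_grid = np.concatenate([[0.0], np.geomspace(1e-5, 10 * max(L.max(), E), 200)])
    chi_grid = np.array([chi2(k) for k in kd_grid])
    k0 = kd_grid[int(np.argmin(chi_grid))]
    lo = kd_grid[max(int(np.argmin(chi_grid)) - 1, 0)]
    hi = kd_grid[min(int(np.argmin(chi_grid)) + 1, len(kd_grid) - 1)]
    if hi > lo:
        res = minimize_scalar(chi2, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            raise FitFailureError(f"K_D profile minimisation failed: {res.message}")
        kd_hat = float(res.x)
        chi2_min = float(res.fun)
    else:  # pragma: no cover - degenerate bracket
        kd_hat, chi2_min = float(k0), float(chi_grid.min())
    if chi2(0.0) < chi2_min:
        kd_hat, chi2_min = 0.0, chi2(0.0)
    amp_hat, _ = amp_and_chi2(kd_hat)

    # noise scale for profile intervals: residual RMS with a floor tied to
    # realistic instrument precision (fraction of the fitted amplitude)
    dof = max(len(L) - 2, 1)
    floor = _SIGMA_FLOOR_REL * max(amp_hat, noise_floor)
    s2 = max(chi2_min / dof, floor**2 * float(np.mean(w)))

    def dchi2(kd: float) -> float:
        return (chi2(kd) - chi2_min) / s2

    status = "ok"
    kd_upper = None
    if dchi2(0.0) <= _DCHI2_95:
        status = "upper_bound_only"
    # 95 % upper limit by root finding above kd_hat
    hi_k = max(kd_hat, 1e-6)
    for _ in range(80):
        if dchi2(hi_k) > _DCHI2_95:
            break
        hi_k *= 2.0
    else:  # pragma: no cover - unbounded profile
        hi_k = np.inf
    if np.isfinite(hi_k) and dchi2(hi_k) > _DCHI2_95:
        lo_k = kd_hat
        kd_upper = float(brentq(lambda k: dchi2(k) - _DCHI2_95, lo_k, hi_k,
                                xtol=1e-10))

    # curvature-based standard errors
    h = max(kd_hat * 1e-3, 1e-6)
    d2 = (chi2(kd_hat + h) - 2 * chi2_min + chi2(max(kd_hat - h, 0.0))) / h**2
    kd_se = float(np.sqrt(2 * s2 / d2)) if d2 > 0 else np.nan
    m_hat = tight_binding_model(L, E, kd_hat, 1.0)
    denom = float(np.sum(w * m_hat * m_hat))
    amp_se = float(np.sqrt(s2 / denom)) if denom > 0 else np.nan

    return BindingFit(
        kd_nM=kd_hat * 1e3,
        kd_se_nM=kd_se * 1e3,
        delta_A_max=amp_hat,
        delta_A_max_se=amp_se,
        status=status,
        kd_upper_nM=None if kd_upper is None else kd_upper * 1e3,
        chi2=chi2_min,
        n_points=len(L),
    )


def highspin_fraction(
    spectrum: Spectrum,
    low_spin_basis: Spectrum,
    high_spin_basis: Spectrum,
) -> float:
    """High-spin fraction by non-negative linear unmixing of basis spectra.

    The sample is modelled as a_LS * LS + a_HS * HS with a_LS, a_HS >= 0
    (non-negative least squares on the sample's wavelength grid, bases
    interpolated as needed); returns a_HS / (a_LS + a_HS).
    """
    grid = spectrum.wavelengths
    ls = np.interp(grid, low_spin_basis.wavelengths, low_spin_basis.absorbance)
    hs = np.interp(grid, high_spin_basis.wavelengths, high_spin_basis.absorbance)
    basis = np.column_stack([ls, hs])
    nls, nhs = np.linalg.norm(ls), np.linalg.norm(hs)
    if nls == 0 or nhs == 0:
        raise DegenerateBasisError("a basis spectrum is identically zero")
    cosang = abs(float(np.dot(ls, hs)) / (nls * nhs))
    if cosang > 1.0 - 1e-12:
        raise DegenerateBasisError(
            "low- and high-spin bases are linearly dependent on this grid"
        )
    coef, _ = nnls(basis, spectrum.absorbance)
    total = coef.sum()
    if total == 0:
        return 0.0
    return float(coef[1] / total)
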