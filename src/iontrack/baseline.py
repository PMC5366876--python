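"""Hydrogen-in-water baseline interaction data.

The package ships a self-contained closed-form surrogate for the
electronic interaction data of hydrogen (a proton/neutral-atom mixture)
slowing down in liquid water:

* **Stopping power** - relativistic Bethe formula (mean excitation
  energy I = 75 eV, unit density) above the stopping maximum, joined
  through a smooth p-norm blend to a velocity-proportional power-law
  branch (S ~ E^0.45) below it.  A small spline-shaped correction factor
  in the 0.25-1.8 MeV decade reshapes the Bethe tail where plain Bethe
  with I = 75 eV deviates from evaluated stopping tables; its constants
  are fixed once so that the integrated proton range at 0.25 MeV and the
  positions of the Barkas-scaled stopping maxima of carbon and neon
  reproduce published stopping-table anchors (see docs/methods.md).

* **Inverse mean free path (IMFP)** for energy-depositing collisions -
  derived from the stopping power and a per-collision energy-transfer
  distribution so that ``imfp * mean_transfer == stopping`` holds
  exactly at every grid point.

* **Energy-transfer distribution** - a truncated inverse-square
  spectrum p(tau) ~ tau^-2 on [tau_min, tau_max(E)], with the upper
  cutoff at the kinematic maximum energy transferable to a free
  electron.  This is a deliberately simple surrogate shape; only its
  mean is constrained by the stopping power.

Users may replace the default with their own table via a three-column
TSV (``energy_MeV_per_u``, ``stopping_keV_per_um``, ``imfp_per_um``).
Queries interpolate log-log linearly and never extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import (
    AMU_MEV,
    BETHE_K,
    ELECTRON_MEV,
    WATER_DENSITY,
    WATER_I_EV,
    WATER_Z_OVER_A,
)

__all__ = [
    "BaselineTable",
    "BaselineFormatError",
    "build_default_baseline",
    "load_baseline",
    "write_baseline",
    "bethe_stopping",
]

# --- closed-form parameterization constants (frozen calibration) -----------

#: Low-energy branch S_L = LOW_BRANCH_COEFF * E^LOW_BRANCH_EXP (keV/um, E in
#: MeV/u); velocity-proportional-like stopping below the maximum.
LOW_BRANCH_EXP = 0.45
LOW_BRANCH_COEFF = 220.0

#: p-norm order of the smooth join between the low branch and the Bethe
#: branch: S = (S_low^-m + S_high^-m)^(-1/m).
JOIN_PNORM = 6.0

#: Energy (MeV/u) of the turnover of the Bethe formula with I = 75 eV;
#: below it the high branch is frozen at its turnover value and the
#: low-energy power law takes over through the p-norm join.
BETHE_TURNOVER_MEV = 0.093

#: Knots (MeV/u) and log-amplitudes of the spline correction factor
#: exp(q(ln E)) applied to the Bethe branch between the first and last
#: knot (q clamps to zero with zero slope outside).  Calibrated once
#: against published stopping anchors; see module docstring.
SHAPE_KNOTS_MEV = (0.14, 0.25, 0.45, 0.90, 1.80)
SHAPE_KNOTS_LOGAMP = (0.0, 0.0, 0.020, 0.008, 0.0)

#: Energy-transfer spectrum: lower cutoff (eV) and minimum ratio of the
#: upper to lower cutoff.
TAU_MIN_EV = 10.0
TAU_RATIO_MIN = 3.0

#: Default grid: log-spaced energies per nucleon (MeV/u).
DEFAULT_GRID_SPAN = (1.0e-3, 300.0)
DEFAULT_GRID_POINTS = 800


class BaselineFormatError(ValueError):
    """Raised when a baseline TSV file is malformed."""


def bethe_stopping(energy_mev_u):
    """Relativistic Bethe electronic stopping of protons in water (keV/um).

    Mean excitation energy I = 75 eV, unit density.  Valid above the
    formula's turnover (~0.1 MeV); returns the raw formula value
    everywhere (negative below ~0.03 MeV).
    """
    e = np.asarray(energy_mev_u, dtype=float)
    gamma = 1.0 + e / AMU_MEV
    beta_sq = 1.0 - 1.0 / gamma**2
    arg = 2.0 * ELECTRON_MEV * 1.0e6 * beta_sq * gamma**2 / WATER_I_EV
    s_mev_cm2_g = (
        BETHE_K * WATER_Z_OVER_A / beta_sq * (np.log(arg) - beta_sq)
    )
    s = s_mev_cm2_g * WATER_DENSITY * 0.1  # MeV/cm -> keV/um
    return s if s.ndim else float(s)


_shape_spline = CubicSpline(
    np.log(SHAPE_KNOTS_MEV), SHAPE_KNOTS_LOGAMP, bc_type="clamped"
)


def _shape_correction(energy_mev_u: np.ndarray) -> np.ndarray:
    """Multiplicative correction exp(q(ln E)); 1 outside the knot span."""
    e = np.asarray(energy_mev_u, dtype=float)
    q = np.where(
        (e >= SHAPE_KNOTS_MEV[0]) & (e <= SHAPE_KNOTS_MEV[-1]),
        _shape_spline(np.log(np.clip(e, SHAPE_KNOTS_MEV[0], SHAPE_KNOTS_MEV[-1]))),
        0.0,
    )
    return np.exp(q)


def _default_stopping(energy_mev_u) -> np.ndarray:
    """Closed-form hydrogen stopping power (keV/um) on any energy array."""
    e = np.asarray(energy_mev_u, dtype=float)
    e_hi = np.maximum(e, BETHE_TURNOVER_MEV)
    s_high = bethe_stopping(e_hi) * _shape_correction(e_hi)
    s_low = LOW_BRANCH_COEFF * e**LOW_BRANCH_EXP
    m = JOIN_PNORM
    return (s_low**-m + s_high**-m) ** (-1.0 / m)


def _kinematic_tau_max_ev(energy_mev_u) -> np.ndarray:
    """Maximum energy (eV) transferable to a free electron, 2 m_e c^2 b^2 g^2."""
    e = np.asarray(energy_mev_u, dtype=float)
    gamma = 1.0 + e / AMU_MEV
    beta_sq_gamma_sq = gamma**2 - 1.0
    return 2.0 * ELECTRON_MEV * 1.0e6 * beta_sq_gamma_sq


def _truncated_invsq_mean(a, b):
    """Mean of p(tau) ~ tau^-2 on [a, b]:  a b ln(b/a) / (b - a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a * b * np.log(b / a) / (b - a)


@dataclass
class BaselineTable:
    """Hydrogen-in-water stopping power and IMFP versus energy per nucleon.

    Attributes
    ----------
    energy_grid : array, MeV/u, strictly increasing
    stopping : array, keV/um, > 0
    imfp : array, um^-1, > 0 (energy-depositing collisions)
    tau_min, tau_max : per-collision energy-transfer spectrum cutoffs
        (eV); the spectrum is p(tau) ~ tau^-2 truncated to [tau_min,
        tau_max], with mean equal to stopping/imfp at each grid point.
    """

    energy_grid: np.ndarray
    stopping: np.ndarray
    imfp: np.ndarray
    tau_min: np.ndarray
    tau_max: np.ndarray
    _log_e: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.stopping = np.asarray(self.stopping, dtype=float)
        self.imfp = np.asarray(self.imfp, dtype=float)
        self.tau_min = np.asarray(self.tau_min, dtype=float)
        self.tau_max = np.asarray(self.tau_max, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.stopping <= 0) or np.any(self.imfp <= 0):
            raise ValueError("stopping and imfp must be positive")
        self._log_e = np.log(self.energy_grid)

    # -- interpolation ------------------------------------------------------

    @property
    def span(self) -> tuple[float, float]:
        return float(self.energy_grid[0]), float(self.energy_grid[-1])

    def _check_span(self, e: np.ndarray) -> None:
        lo, hi = self.span
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside baseline span [{lo:g}, {hi:g}] MeV/u; "
                "no extrapolation is performed"
            )

    def _loglog(self, energy_mev_u, values: np.ndarray):
        e = np.asarray(energy_mev_u, dtype=float)
        self._check_span(e)
        out = np.exp(np.interp(np.log(e), self._log_e, np.log(values)))
        return out if out.ndim else float(out)

    def stopping_at(self, energy_mev_u):
        """Electronic stopping power (keV/um), log-log interpolated."""
        return self._loglog(energy_mev_u, self.stopping)

    def imfp_at(self, energy_mev_u):
        """Total IMFP (um^-1) for energy-depositing collisions."""
        return self._loglog(energy_mev_u, self.imfp)

    def mean_transfer_at(self, energy_mev_u):
        """Mean energy transfer per collision (eV) = stopping / imfp."""
        s = np.asarray(self.stopping_at(energy_mev_u))
        lam = np.asarray(self.imfp_at(energy_mev_u))
        m = s * 1000.0 / lam  # keV/um -> eV/um
        return m if m.ndim else float(m)

    # -- transfer sampling --------------------------------------------------

    def transfer_cutoffs_at(self, energy_mev_u):
        """Spectrum cutoffs (tau_min, tau_max) in eV at arbitrary energy."""
        a = self._loglog(energy_mev_u, self.tau_min)
        b = self._loglog(energy_mev_u, self.tau_max)
        return a, b

    def sample_transfer(self, energy_mev_u: float, rng: np.random.Generator,
                        size=None):
        """Draw per-collision energy transfers (eV) at energy E.

        Inverse-CDF sampling of the truncated inverse-square spectrum.
        The empirical mean over many draws approximates
        ``stopping_at(E)/imfp_at(E)`` (exactly at grid points).
        """
        a, b = self.transfer_cutoffs_at(energy_mev_u)
        u = rng.random(size)
        return a / (1.0 - u * (1.0 - a / b))

    # -- serialization ------------------------------------------------------

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "energy_MeV_per_u": self.energy_grid,
                "stopping_keV_per_um": self.stopping,
                "imfp_per_um": self.imfp,
            }
        )


def _cutoffs_from_mean(mean_ev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the truncated-spectrum cutoffs for prescribed mean transfers.

    Keeps tau_min at 10 eV where possible (lowering it to mean/2 for very
    soft spectra) and solves tau_max from the mean by bisection on
    log(tau_max).
    """
    mean_ev = np.asarray(mean_ev, dtype=float)
    a = np.minimum(TAU_MIN_EV, mean_ev / 2.0)
    # mean is monotone increasing in b; bracket then bisect in log-space
    lo = np.log(a * 1.0001)
    hi = np.log(np.maximum(a * 10.0, mean_ev * 4.0))
    for _ in range(200):
        m = _truncated_invsq_mean(a, np.exp(hi))
        grow = m < mean_ev
        if not np.any(grow):
            break
        hi = np.where(grow, hi + 0.5, hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        m = _truncated_invsq_mean(a, np.exp(mid))
        lo = np.where(m < mean_ev, mid, lo)
        hi = np.where(m < mean_ev, hi, mid)
    return a, np.exp(0.5 * (lo + hi))


def build_default_baseline(
    span: tuple[float, float] = DEFAULT_GRID_SPAN,
    n_points: int = DEFAULT_GRID_POINTS,
) -> BaselineTable:
    """Build the packaged closed-form hydrogen baseline table.

    The IMFP is derived from the stopping power and the analytic mean of
    the transfer spectrum so that ``imfp * mean_transfer == stopping``
    holds to machine precision at every grid point.
    """
    grid = np.geomspace(span[0], span[1], n_points)
    stopping = _default_stopping(grid)
    tau_max = np.maximum(_kinematic_tau_max_ev(grid),
                         TAU_RATIO_MIN * TAU_MIN_EV)
    tau_min = np.full_like(grid, TAU_MIN_EV)
    mean_tau = _truncated_invsq_mean(tau_min, tau_max)
    imfp = stopping * 1000.0 / mean_tau  # (eV/um) / eV -> um^-1
    return BaselineTable(grid, stopping, imfp, tau_min, tau_max)


def write_baseline(table: BaselineTable, path) -> None:
    """Write a baseline table as tab-separated text."""
    table.to_frame().to_csv(path, sep="\t", index=False,
                            float_format="%.10g")


def load_baseline(path) -> BaselineTable:
    """Load and validate a baseline TSV.

    Expects a header line with columns ``energy_MeV_per_u``,
    ``stopping_keV_per_um``, ``imfp_per_um``.  Rows are sorted by
    energy; duplicate energies, non-positive values, and malformed rows
    raise :class:`BaselineFormatError` naming the offending line.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["energy_MeV_per_u", "stopping_keV_per_um", "imfp_per_um"]
        if header != expected:
            raise BaselineFormatError(
                f"line 1: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise BaselineFormatError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                e, s, lam = (float(p) for p in parts)
            except ValueError:
                raise BaselineFormatError(
                    f"line {lineno}: non-numeric value in {parts!r}"
                ) from None
            if not (np.isfinite(e) and np.isfinite(s) and np.isfinite(lam)):
                raise BaselineFormatError(f"line {lineno}: non-finite value")
            if e <= 0 or s <= 0 or lam <= 0:
                raise BaselineFormatError(
                    f"line {lineno}: values must be positive"
                )
            rows.append((lineno, e, s, lam))
    if len(rows) < 2:
        raise BaselineFormatError("table needs at least 2 rows")
    rows.sort(key=lambda r: r[1])
    for (ln_a, e_a, *_), (ln_b, e_b, *_) in zip(rows, rows[1:]):
        if e_a == e_b:
            raise BaselineFormatError(
                f"line {ln_b}: duplicate energy {e_b:g} (also line {ln_a})"
            )
    arr = np.array([(e, s, lam) for _, e, s, lam in rows])
    mean_tau = arr[:, 1] * 1000.0 / arr[:, 2]
    tau_min, tau_max = _cutoffs_from_mean(mean_tau)
    return BaselineTable(arr[:, 0], arr[:, 1], arr[:, 2], tau_min, tau_max)
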