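"""Four-parameter logistic dose-response fitting and inhibitory concentrations.

Viability is expressed as percent of vehicle (vehicle = 100%).  The model is

    v(c) = bottom + (top - bottom) / (1 + (c / ic50) ** hill)

with ``hill > 0`` so that viability decreases with concentration.  IC50 is
the concentration at half-maximal response between ``top`` and ``bottom``;
ICx for any other inhibition level follows in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "four_pl",
    "fit_four_pl",
    "inhibitory_concentration",
    "fit_panel",
]

#: Default box constraints: (top, bottom, hill) bounds chosen to stabilise
#: IC50 extrapolation beyond the tested dose grid.
DEFAULT_CONSTRAINTS = {
    "top": (80.0, 120.0),
    "bottom": (0.0, 50.0),
    "hill": (1e-3, 10.0),
}

#: Response range (percentage points) below which a curve is declared
#: non-responsive rather than fitted.
FLAT_TOLERANCE = 5.0


@dataclass
class DoseResponseFit:
    """Result of a 4PL fit for one cell line."""

    top: float
    bottom: float
    hill: float
    ic50: float
    rss: float
    converged: bool
    reason: str = ""
    line: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.converged:
            if not self.ic50 > 0:
                raise ValueError("converged fit requires ic50 > 0")
            if not self.top > self.bottom:
                raise ValueError("converged fit requires top > bottom")


def four_pl(conc: np.ndarray, top: float, bottom: float, hill: float, ic50: float) -> np.ndarray:
    """Evaluate the four-parameter logistic at concentrations ``conc``."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def fit_four_pl(
    concentrations,
    viability,
    constraints: dict | None = None,
    n_starts: int = 12,
    flat_tolerance: float = FLAT_TOLERANCE,
) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialisation over IC50.

    Parameters
    ----------
    concentrations, viability
        Matched arrays; concentrations in uM (strictly positive), viability
        in percent of vehicle.  At least 4 distinct concentrations required.
    constraints
        Optional overrides for the ``top`` / ``bottom`` / ``hill`` bounds.
    n_starts
        Number of log-spaced IC50 starting values spanning the dose range
        extended by a factor 10 on each side; the lowest-RSS solution wins,
        ties broken by smallest IC50.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if conc.shape != viab.shape:
        raise ValueError("concentrations and viability must have equal length")
    if np.unique(conc).size < 4:
        raise ValueError("at least 4 distinct concentrations are required")
    if not np.all(np.isfinite(viab)):
        raise ValueError("viability values must be finite")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")

    if viab.max() - viab.min() < flat_tolerance:
        return DoseResponseFit(
            top=float(viab.mean()), bottom=float(viab.mean()), hill=float("nan"),
            ic50=float("nan"), rss=float(np.sum((viab - viab.mean()) ** 2)),
            converged=False, reason="non-responsive",
        )

    bnds = dict(DEFAULT_CONSTRAINTS)
    if constraints:
        bnds.update(constraints)
    log_ic50_lo = math.log10(conc.min()) - 2.0
    log_ic50_hi = math.log10(conc.max()) + 2.0

    # parameter vector: (top, bottom, hill, log10_ic50)
    lower = np.array([bnds["top"][0], bnds["bottom"][0], bnds["hill"][0], log_ic50_lo])
    upper = np.array([bnds["top"][1], bnds["bottom"][1], bnds["hill"][1], log_ic50_hi])

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, bottom, hill, log_ic50 = theta
        return four_pl(conc, top, bottom, hill, 10.0 ** log_ic50) - viab

    top0 = float(np.clip(viab.max(), *bnds["top"]))
    bottom0 = float(np.clip(viab.min(), *bnds["bottom"]))
    starts = np.linspace(math.log10(conc.min()) - 1.0, math.log10(conc.max()) + 1.0, n_starts)

    best: tuple[float, float, np.ndarray] | None = None  # (rss, ic50, theta)
    any_success = False
    for s in starts:
        theta0 = np.clip(np.array([top0, bottom0, 1.0, s]), lower, upper)
        sol = least_squares(residuals, theta0, bounds=(lower, upper), method="trf")
        if not sol.success:
            continue
        any_success = True
        rss = float(np.sum(sol.fun ** 2))
        ic50 = 10.0 ** sol.x[3]
        key = (rss, ic50, sol.x)
        if best is None or rss < best[0] - 1e-12 or (abs(rss - best[0]) <= 1e-12 and ic50 < best[1]):
            best = key
    if not any_success or best is None:
        return DoseResponseFit(
            top=float("nan"), bottom=float("nan"), hill=float("nan"), ic50=float("nan"),
            rss=float("inf"), converged=False, reason="optimizer failed",
        )
    rss, ic50, theta = best
    return DoseResponseFit(
        top=float(theta[0]), bottom=float(theta[1]), hill=float(theta[2]),
        ic50=float(ic50), rss=rss, converged=True,
    )


def inhibitory_concentration(fit: DoseResponseFit, inhibition_level: float) -> float:
    """Concentration producing the given fractional inhibition of (top-bottom).

    Closed form: ``c = ic50 * (level / (1 - level)) ** (1 / hill)``; the level
    0.5 returns IC50 exactly.
    """
    if not fit.converged:
        raise ValueError("inhibitory concentration undefined for non-converged fit")
    if not 0.0 < inhibition_level < 1.0:
        raise ValueError("inhibition_level must lie strictly between 0 and 1")
    return float(fit.ic50 * (inhibition_level / (1.0 - inhibition_level)) ** (1.0 / fit.hill))


def fit_panel(viability: pd.DataFrame, agent: str = "etoposide") -> pd.DataFrame:
    """Fit 4PL curves per cell line from a long-format viability table.

    Expects columns ``line, agent, concentration_uM, replicate, viability_pct``
    and returns one row per line with fitted parameters plus IC25.
    """
    rows = []
    sub = viability[viability["agent"] == agent]
    if sub.empty:
        raise ValueError(f"no viability rows for agent {agent!r}")
    for line, grp in sub.groupby("line", sort=True):
        fit = fit_four_pl(grp["concentration_uM"].to_numpy(), grp["viability_pct"].to_numpy())
        fit.line = str(line)
        ic25 = inhibitory_concentration(fit, 0.25) if fit.converged else float("nan")
        rows.append(
            {
                "line": str(line),
                "top": fit.top,
                "bottom": fit.bottom,
                "hill": fit.hill,
                "ic50_uM": fit.ic50,
                "ic25_uM": ic25,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
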