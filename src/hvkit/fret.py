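"""FRET-based subunit stoichiometry of fluorescent-protein-tagged channels.

Cells co-expressing donor- and acceptor-tagged subunits assemble channels
with a binomial mix of tag combinations.  For a dimer, a given donor has
an acceptor partner with probability f_A equal to the acceptor fraction
of expressed subunits; the population-average apparent FRET efficiency
is then E_app = E_max * f_A, where E_max is the pairwise efficiency of a
single donor-acceptor pair.  Expressing f_A through the measured
donor/acceptor intensity ratio r = I_d/I_a and a brightness ratio rho
(acceptor vs donor signal per subunit) gives

    E_app(r) = E_max / (1 + rho * r)

which decays from E_max in acceptor-dominated cells to 0 in
donor-dominated ones.  The pairwise efficiency converts to a fluorophore
separation through the Forster relation R = R0 * (1/E - 1)^(1/6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FretSample",
    "DimerFretModel",
    "dimer_eapp",
    "bin_by_ratio",
    "fit_dimer_model",
    "forster_distance",
    "forster_efficiency",
]


@dataclass(frozen=True)
class FretSample:
    """Per-cell FRET measurement: donor and acceptor intensities
    (arbitrary units, same scale) and the apparent FRET efficiency."""

    I_d: float
    I_a: float
    E_app: float

    def __post_init__(self) -> None:
        if self.I_d < 0 or self.I_a < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def ratio(self) -> float:
        if self.I_a <= 0:
            raise ValueError("intensity ratio undefined for I_a = 0")
        return self.I_d / self.I_a


@dataclass(frozen=True)
class DimerFretModel:
    """Random-assembly dimer FRET model.

    ``E_max``: pairwise donor-acceptor efficiency in (0, 1);
    ``rho``: acceptor-to-donor brightness ratio (> 0);
    ``R0``: Forster radius in angstroms (configuration, never fitted).
    """

    E_max: float
    rho: float = 1.0
    R0: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.E_max < 1.0:
            raise ValueError(f"E_max must lie in (0, 1), got {self.E_max}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.R0 is not None and self.R0 <= 0:
            raise ValueError(f"R0 must be positive, got {self.R0}")


def dimer_eapp(ratio, model: DimerFretModel):
    """Apparent FRET efficiency of a dimer population at donor/acceptor
    intensity ratio ``ratio``; strictly decreasing, E_max at ratio 0."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("intensity ratio must be non-negative")
    out = model.E_max / (1.0 + model.rho * r)
    return float(out) if out.ndim == 0 else out


def bin_by_ratio(samples: Sequence[FretSample], bin_width: float = 0.1) -> pd.DataFrame:
    """Average E_app in consecutive I_d/I_a windows of ``bin_width``.

    Returns columns ``ratio`` (the mean ratio of the cells in the bin,
    which avoids the first-order bias a fixed bin center would add on a
    curved model), ``E_app_mean``, ``E_app_sem``, ``n``.
    """
    ratios = np.array([s.ratio for s in samples])
    eapps = np.array([s.E_app for s in samples])
    edges = np.arange(0.0, ratios.max() + bin_width, bin_width)
    idx = np.digitize(ratios, edges) - 1
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        n = int(sel.sum())
        rows.append(
            {
                "ratio": float(ratios[sel].mean()),
                "E_app_mean": float(eapps[sel].mean()),
                "E_app_sem": float(eapps[sel].std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def fit_dimer_model(
    samples: Sequence[FretSample],
    bin_width: float = 0.1,
    R0: Optional[float] = None,
) -> DimerFretModel:
    """Fit E_max and rho of the random-assembly dimer model to a cell
    population, after binning by intensity ratio.

    Bins are weighted by their sem when at least two cells contribute.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 cells spanning a ratio range")
    binned = bin_by_ratio(samples, bin_width)
    if len(binned) < 3:
        raise ValueError(f"only {len(binned)} ratio bins; need >= 3")
    sigma = binned["E_app_sem"].to_numpy()
    use_sigma = np.all(np.isfinite(sigma)) and np.all(sigma > 0)

    def model(r, e_max, rho):
        return e_max / (1.0 + rho * r)

    popt, _ = curve_fit(
        model,
        binned["ratio"].to_numpy(),
        binned["E_app_mean"].to_numpy(),
        p0=[max(binned["E_app_mean"].max(), 0.05), 1.0],
        sigma=sigma if use_sigma else None,
        bounds=([1e-6, 1e-6], [0.999999, np.inf]),
        maxfev=20000,
    )
    return DimerFretModel(E_max=float(popt[0]), rho=float(popt[1]), R0=R0)


def forster_distance(E: float, R0: float) -> float:
    """Fluorophore separation implied by a pairwise efficiency:
    R = R0 * (1/E - 1)^(1/6); R = R0 at E = 1/2."""
    if not 0.0 < E < 1.0:
        raise ValueError(f"efficiency must lie strictly in (0, 1), got {E}")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def forster_efficiency(R: float, R0: float) -> float:
    """Inverse of :func:`forster_distance`: E = 1/(1 + (R/R0)^6)."""
    if R < 0 or R0 <= 0:
        raise ValueError("distances must be positive")
    return 1.0 / (1.0 + (R / R0) ** 6)
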