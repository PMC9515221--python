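"""Dose-checkerboard log-odds synergy scoring and 4PL dose-response fits.

Under Bliss independence the survival fraction of a drug combination equals
the product of the single-agent survival fractions.  The synergy statistic
for a combination cell is

    L(a, b) = log_base( f_AB / (f_A * f_B) )

on fractional growth (survival relative to vehicle): L = 0 is additive,
L < 0 synergy (observed growth below the Bliss product), L > 0 antagonism.
Single-agent potency is summarised by a four-parameter logistic (4PL) fit
with the IC50 classifying lines as sensitive (< 5 uM) or less sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from tribescreen.errors import FitError, SchemaError

CLIP_EPS = 1e-4


@dataclass
class DoseResponseMatrix:
    """Checkerboard viability fractions with replicate layers.

    ``viability`` has shape (replicates, len(doses_a), len(doses_b)); doses
    ascend and include 0 (the single-agent margins); each replicate layer is
    normalised so the vehicle cell v(0, 0) is exactly 1.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if v.ndim == 2:
            v = v[None, :, :]
        if v.ndim != 3:
            raise ValueError("viability must be a (replicate, doses_a, doses_b) array")
        self.viability = v
        if (self.doses_a < 0).any() or (self.doses_b < 0).any():
            raise ValueError("doses must be nonnegative")
        # sort doses ascending, carrying the grid along
        ia, ib = np.argsort(self.doses_a), np.argsort(self.doses_b)
        self.doses_a = self.doses_a[ia]
        self.doses_b = self.doses_b[ib]
        self.viability = self.viability[:, ia][:, :, ib]
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise SchemaError("dose grids must include the single-agent margins (dose 0)")
        if np.any(np.diff(self.doses_a) <= 0) or np.any(np.diff(self.doses_b) <= 0):
            raise ValueError("doses must be strictly increasing")
        v00 = self.viability[:, 0, 0]
        if (v00 <= 0).any():
            raise ValueError("vehicle viability must be positive")
        self.viability = self.viability / v00[:, None, None]

    @classmethod
    def from_long(cls, df: pd.DataFrame, drug_a: str = "A", drug_b: str = "B"):
        """Build from a long table (drug_a_dose, drug_b_dose, replicate, viability)."""
        da = np.sort(df["drug_a_dose"].unique())
        db = np.sort(df["drug_b_dose"].unique())
        reps = np.sort(df["replicate"].unique())
        grid = np.full((len(reps), len(da), len(db)), np.nan)
        ri = {r: i for i, r in enumerate(reps)}
        ai = {d: i for i, d in enumerate(da)}
        bi = {d: i for i, d in enumerate(db)}
        for row in df.itertuples(index=False):
            grid[ri[row.replicate], ai[row.drug_a_dose], bi[row.drug_b_dose]] = row.viability
        if np.isnan(grid).any():
            raise SchemaError("incomplete checkerboard: missing (dose, dose, replicate) cells")
        return cls(drug_a, drug_b, da, db, grid)


@dataclass
class SynergyResult:
    """Log-odds grid over the positive-dose combinations."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    log_odds: np.ndarray  # shape (len(doses_a), len(doses_b)), NaN where clipped/excluded
    min: float
    max: float
    base: float
    n_clipped: int = 0
    argmin: tuple[float, float] | None = None
    argmax: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_odds, index=self.doses_a, columns=self.doses_b)


def fractional_growth(treated, vehicle, eps: float = CLIP_EPS):
    """Survival fraction treated/vehicle, clipped into (eps, 1].

    Returns (fraction, clipped) where ``clipped`` marks values that were
    pushed back into range (complete kill or growth above vehicle).
    """
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    if np.any(vehicle <= 0):
        raise ValueError("vehicle signal must be positive")
    frac = treated / vehicle
    clipped = (frac <= eps) | (frac > 1.0)
    return np.clip(frac, eps, 1.0), clipped


def log_odds(f_a, f_b, f_ab, base: float = 10.0):
    """Bliss log-odds: log_base(f_AB / (f_A * f_B)) on survival fractions.

    Zero iff the combination matches Bliss independence exactly; negative
    means synergy, positive antagonism.
    """
    f_a, f_b, f_ab = (np.asarray(f, dtype=float) for f in (f_a, f_b, f_ab))
    if np.any(f_a <= 0) or np.any(f_b <= 0) or np.any(f_ab <= 0):
        raise ValueError("fractions must be in (0, 1]; clip upstream")
    if np.any(f_a > 1) or np.any(f_b > 1) or np.any(f_ab > 1):
        raise ValueError("fractions must be in (0, 1]")
    return np.log(f_ab / (f_a * f_b)) / np.log(base)


def log_odds_inhibition(f_a, f_b, f_ab, base: float = 10.0):
    """Literal growth-inhibition reading of the same statistic.

    Scores log_base(i_AB / (i_A * i_B)) on inhibition fractions i = 1 - f.
    Kept for comparison; under this reading a synergistic combination scores
    positive, the opposite of the survival convention used by
    :func:`log_odds`.
    """
    i_a, i_b, i_ab = (1.0 - np.asarray(f, dtype=float) for f in (f_a, f_b, f_ab))
    i_a, i_b, i_ab = (np.clip(i, CLIP_EPS, 1.0) for i in (i_a, i_b, i_ab))
    return np.log(i_ab / (i_a * i_b)) / np.log(base)


def synergy_grid(
    matrix: DoseResponseMatrix,
    base: float = 10.0,
    include_clipped: bool = False,
    inhibition_mode: bool = False,
) -> SynergyResult:
    """Replicate-averaged log-odds over every positive-dose combination.

    Cells whose fractions were clipped (complete kill) are excluded from the
    min/max summaries unless ``include_clipped``.
    """
    f = matrix.viability.mean(axis=0)
    f, clipped = fractional_growth(f, 1.0)
    na, nb = len(matrix.doses_a) - 1, len(matrix.doses_b) - 1
    if na < 1 or nb < 1:
        raise SchemaError("need at least one positive dose of each drug")
    score = log_odds_inhibition if inhibition_mode else log_odds
    grid = np.full((na, nb), np.nan)
    cell_clipped = np.zeros((na, nb), dtype=bool)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            grid[i - 1, j - 1] = score(f[i, 0], f[0, j], f[i, j], base=base)
            cell_clipped[i - 1, j - 1] = clipped[i, 0] | clipped[0, j] | clipped[i, j]
    usable = grid if include_clipped else np.where(cell_clipped, np.nan, grid)
    if np.isnan(usable).all():
        raise FitError("every combination cell was clipped; nothing to summarise")
    imin = np.unravel_index(np.nanargmin(usable), usable.shape)
    imax = np.unravel_index(np.nanargmax(usable), usable.shape)
    return SynergyResult(
        doses_a=matrix.doses_a[1:], doses_b=matrix.doses_b[1:], log_odds=grid,
        min=float(usable[imin]), max=float(usable[imax]), base=base,
        n_clipped=int(cell_clipped.sum()),
        argmin=(float(matrix.doses_a[1:][imin[0]]), float(matrix.doses_b[1:][imin[1]])),
        argmax=(float(matrix.doses_a[1:][imax[0]]), float(matrix.doses_b[1:][imax[1]])),
    )


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ic50: float
    rss: float
    extrapolated: bool = False


def four_pl(dose, top, bottom, hill, ic50):
    """4PL decreasing viability curve: bottom + (top-bottom)/(1 + (d/IC50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_4pl(doses, responses, n_starts: int = 8) -> FourPLFit:
    """Bounded multi-start least-squares 4PL fit.

    Requires >= 4 distinct positive doses; responses are viability fractions
    in [0, 1.2].  IC50 starts span the positive dose range on a log grid; an
    IC50 landing outside that range is flagged extrapolated.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    pos = doses > 0
    if len(np.unique(doses[pos])) < 4:
        raise FitError("need at least 4 distinct positive doses for a 4PL fit")
    if np.any((responses < 0) | (responses > 1.2)):
        raise FitError("responses must be viability fractions in [0, 1.2]")

    d_lo, d_hi = doses[pos].min(), doses[pos].max()
    bounds_lo = [0.5, 0.0, 0.1, d_lo / 100.0]
    bounds_hi = [1.2, 0.5, 10.0, d_hi * 100.0]

    def residuals(theta):
        return four_pl(doses, *theta) - responses

    best = None
    for ic50_0 in np.geomspace(d_lo, d_hi, n_starts):
        theta0 = [max(responses.max(), 0.5), max(min(responses.min(), 0.5), 0.0), 1.0, ic50_0]
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(bounds_lo, bounds_hi))
        except ValueError:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise FitError("4PL fit failed to converge from any start")
    rss, (top, bottom, hill, ic50) = best
    return FourPLFit(
        top=float(top), bottom=float(bottom), hill=float(hill), ic50=float(ic50),
        rss=rss, extrapolated=not (d_lo <= ic50 <= d_hi),
    )


def classify_sensitivity(ic50: float, threshold: float = 5.0) -> str:
    """Sensitive below the IC50 threshold (5 uM by default), else less-sensitive."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return "sensitive" if ic50 < threshold else "less-sensitive"
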