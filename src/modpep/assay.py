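"""Critical aggregation concentration (CAC) from ThT titration curves.

Thioflavin T fluorescence stays near baseline below the CAC and rises
steeply once beta-sheet assemblies form.  The CAC is estimated as the
breakpoint of a continuous two-segment linear model on log2 concentration:

    F(x) = b0 + b1 * x + b2 * max(0, x - xb),     x = log2(c / 1 uM)

fitted by least squares with the breakpoint searched on a dense grid over
the interior dose range and polished by bounded scalar minimization.  The
aggregation call is valid only when the post-breakpoint slope exceeds the
pre-breakpoint slope (b2 > 0) and the two-segment model improves
significantly on a single line (F test); otherwise the estimate is
censored as ">= max tested" — the convention used for designs that show no
fluorescence rise over the tested range.

The onset concentration (first tested dose at or above the fitted
breakpoint) is reported alongside; the breakpoint is the primary estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class AssayError(ValueError):
    pass


@dataclass
class TitrationCurve:
    concentrations: np.ndarray         # uM, strictly increasing, >= 5 points
    fluorescence: np.ndarray           # arbitrary units, >= 0
    molecule: str = ""
    replicate: str | int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.concentrations.shape != self.fluorescence.shape:
            raise AssayError("concentration and fluorescence lengths differ")
        if len(self.concentrations) < 5:
            raise AssayError("need at least 5 doses")
        if np.any(self.concentrations <= 0):
            raise AssayError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise AssayError("concentrations must be strictly increasing")


@dataclass
class CACEstimate:
    molecule: str
    cac: float | None                  # uM; None when censored
    censored: bool
    max_tested: float                  # uM
    pre_slope: float                   # AU per log2 concentration unit
    post_slope: float
    rss: float
    p_value: float
    onset: float | None = None         # first tested dose >= breakpoint
    ci: tuple | None = None            # optional bootstrap CI (not computed by default)
    replicate: str | int = 0

    @property
    def display(self) -> str:
        if self.censored:
            return f">= {self.max_tested:g} uM"
        return f"{self.cac:g} uM"


@dataclass(frozen=True)
class FitOptions:
    grid_size: int = 200               # breakpoint candidates across interior doses
    alpha: float = 0.01                # F-test significance for a valid breakpoint


def _hinge_fit(x: np.ndarray, y: np.ndarray, xb: float) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - xb)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def fit_cac(curve: TitrationCurve, options: FitOptions = FitOptions()
            ) -> CACEstimate:
    """Two-segment breakpoint estimate of the CAC for one titration curve."""
    x = np.log2(curve.concentrations)
    y = curve.fluorescence
    n = len(x)

    lo, hi = x[1], x[-2]               # interior breakpoints only
    grid = np.linspace(lo, hi, options.grid_size)
    rss_grid = np.array([_hinge_fit(x, y, xb)[1] for xb in grid])
    k = int(np.argmin(rss_grid))

    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if b > a:
        res = optimize.minimize_scalar(
            lambda xb: _hinge_fit(x, y, xb)[1], bounds=(a, b), method="bounded",
            options={"xatol": 1e-10})
        xb = float(res.x)
        beta, rss = _hinge_fit(x, y, xb)
        if rss_grid[k] < rss:          # guard against a flat valley
            xb, (beta, rss) = grid[k], _hinge_fit(x, y, grid[k])
    else:                              # pragma: no cover
        xb, (beta, rss) = grid[k], _hinge_fit(x, y, grid[k])

    # single-line null model
    X0 = np.column_stack([np.ones_like(x), x])
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))

    pre_slope, post_slope = float(beta[1]), float(beta[1] + beta[2])
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:                     # perfectly flat signal
        p_value = 1.0
    elif rss < 1e-12 * tss:            # two-segment model fits perfectly
        p_value = 0.0 if (rss0 - rss) > 1e-12 * tss else 1.0
    else:
        f_stat = ((rss0 - rss) / 2.0) / (rss / max(n - 4, 1))
        p_value = float(stats.f.sf(max(f_stat, 0.0), 2, max(n - 4, 1)))

    valid = beta[2] > 0 and p_value < options.alpha
    max_tested = float(curve.concentrations[-1])
    if not valid:
        return CACEstimate(
            molecule=curve.molecule, cac=None, censored=True,
            max_tested=max_tested, pre_slope=pre_slope, post_slope=post_slope,
            rss=rss, p_value=p_value, replicate=curve.replicate)
    cac = float(2.0 ** xb)
    above = curve.concentrations[curve.concentrations >= cac - 1e-9]
    onset = float(above[0]) if len(above) else None
    return CACEstimate(
        molecule=curve.molecule, cac=cac, censored=False,
        max_tested=max_tested, pre_slope=pre_slope, post_slope=post_slope,
        rss=rss, p_value=p_value, onset=onset, replicate=curve.replicate)


def batch_cac(curves: list[TitrationCurve],
              options: FitOptions = FitOptions()) -> pd.DataFrame:
    """Fit every curve; one row per (molecule, replicate)."""
    rows = []
    for curve in curves:
        est = fit_cac(curve, options)
        rows.append({
            "molecule": est.molecule,
            "replicate": est.replicate,
            "cac_uM": est.cac,
            "censored": est.censored,
            "cac_display": est.display,
            "onset_uM": est.onset,
            "pre_slope": round(est.pre_slope, 4),
            "post_slope": round(est.post_slope, 4),
            "rss": round(est.rss, 6),
            "p_value": est.p_value,
        })
    return pd.DataFrame(rows, columns=[
        "molecule", "replicate", "cac_uM", "censored", "cac_display",
        "onset_uM", "pre_slope", "post_slope", "rss", "p_value"])


def read_titration_csv(path_or_buffer) -> list[TitrationCurve]:
    """Load curves from CSV with columns concentration, fluorescence,
    molecule[, replicate]."""
    df = pd.read_csv(path_or_buffer)
    required = {"concentration", "fluorescence"}
    if not required <= set(df.columns):
        raise AssayError(f"CSV must provide columns {sorted(required)}")
    if "molecule" not in df:
        df["molecule"] = ""
    if "replicate" not in df:
        df["replicate"] = 0
    curves = []
    for (mol, rep), g in df.groupby(["molecule", "replicate"], sort=False):
        g = g.sort_values("concentration")
        curves.append(TitrationCurve(
            concentrations=g["concentration"].to_numpy(),
            fluorescence=g["fluorescence"].to_numpy(),
            molecule=str(mol), replicate=rep))
    return curves
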