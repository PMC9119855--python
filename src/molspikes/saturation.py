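"""Asymptotic saturation fitting for pool-complexity and per-well molecule estimates.

The number of distinct molecules observed grows with sequencing effort and
saturates at the true number present.  The model fitted throughout is the
asymptotic regression

    y(x) = b0 + b1 * (1 - exp(-exp(c) * x))

whose asymptote b0 + b1 estimates the total complexity (of the whole spike
pool when x counts molecules sequenced across cells, or of a single well when
x counts subsampled reads).  Empty wells — wells that received spike-ins but
no cell — are identified from their mapped-read composition and used to
estimate how many spike molecules were dispensed per well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .collapse import collapsed_unique_count, encode_umis


class SaturationFitError(RuntimeError):
    """Raised when the asymptotic fit fails to converge; carries the best fit found."""

    def __init__(self, message: str, best_fit: "SaturationFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class SaturationFit:
    """Coefficients of the asymptotic model y = b0 + b1*(1 - exp(-exp(c)*x))."""

    b0: float
    b1: float
    c: float
    residual_sse: float = 0.0
    asymptote_se: float = float("nan")
    converged: bool = True
    seed: int | None = None

    @property
    def asymptote(self) -> float:
        return self.b0 + self.b1

    def predict(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        y = self.b0 + self.b1 * (1.0 - np.exp(-np.exp(self.c) * x))
        return float(y) if y.ndim == 0 else y


def _model(x, b0, b1, c):
    return b0 + b1 * (1.0 - np.exp(-np.exp(c) * x))


def fit_asymptotic(x, y) -> SaturationFit:
    """Least-squares fit of the asymptotic saturation model.

    Requires >= 4 points with strictly increasing x.  Starts from
    b0 = min(y), b1 = max(y) - min(y), c = log(1/median(x)) and retries from
    5 deterministically jittered starts on failure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("fit_asymptotic requires at least 4 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    b0_0 = float(y.min())
    b1_0 = float(y.max() - y.min())
    c_0 = float(np.log(1.0 / np.median(x[x > 0]))) if np.any(x > 0) else 0.0
    if b1_0 == 0.0:
        # constant response: the asymptote is that constant
        return SaturationFit(b0=b0_0, b1=0.0, c=c_0, residual_sse=0.0, asymptote_se=0.0)
    jitters = [(1.0, 1.0, 0.0), (0.5, 1.5, 1.0), (1.5, 0.8, -1.0), (1.0, 2.0, 2.0),
               (0.0, 1.2, 0.5)]
    last_err: Exception | None = None
    for jb0, jb1, jc in jitters:
        try:
            p0 = [b0_0 * jb0, b1_0 * jb1, c_0 + jc]
            popt, pcov = curve_fit(_model, x, y, p0=p0, maxfev=20000)
            resid = y - _model(x, *popt)
            sse = float(np.sum(resid ** 2))
            var_asym = pcov[0, 0] + pcov[1, 1] + 2 * pcov[0, 1]
            se = float(np.sqrt(var_asym)) if np.isfinite(var_asym) and var_asym >= 0 else float("nan")
            return SaturationFit(
                b0=float(popt[0]), b1=float(popt[1]), c=float(popt[2]),
                residual_sse=sse, asymptote_se=se,
            )
        except RuntimeError as err:  # curve_fit non-convergence
            last_err = err
    best = SaturationFit(b0=b0_0, b1=b1_0, c=c_0, converged=False)
    raise SaturationFitError(f"asymptotic fit did not converge: {last_err}", best)


def estimate_pool_complexity(per_cell_spumis: dict[str, "list[str]"]) -> SaturationFit:
    """Estimate the distinct-molecule complexity of the whole spike pool.

    ``per_cell_spumis`` maps each cell to its error-corrected spUMI list.
    Cells are accumulated in sorted order; x is the cumulative number of
    spUMI molecules sequenced, y the cumulative number of distinct sequences.
    The fitted asymptote estimates the pool complexity.
    """
    xs, ys = [], []
    seen: set[str] = set()
    total = 0
    for cell in sorted(per_cell_spumis):
        spumis = per_cell_spumis[cell]
        total += len(spumis)
        seen.update(spumis)
        xs.append(total)
        ys.append(len(seen))
    fit = fit_asymptotic(xs, ys)
    if np.isfinite(fit.asymptote_se) and fit.asymptote_se > 0.5 * abs(fit.asymptote):
        warnings.warn(
            "pool far from saturation: asymptote uncertainty exceeds 50% of the estimate"
        )
    return fit


def estimate_well_molecules(
    well_reads: "pd.Series | list[str]",
    depths: "list[int] | None" = None,
    seed: int = 0,
    d: int = 2,
) -> tuple[SaturationFit, pd.DataFrame]:
    """Estimate the number of spike molecules captured in one (empty) well.

    ``well_reads`` holds one observed spUMI sequence per sequenced read of
    the well.  At each depth, reads are subsampled without replacement
    (seeded), spUMIs are adjacency-corrected at Hamming distance ``d`` and
    distinct molecules counted; the asymptote of the fitted depth-molecule
    relationship is the number of captured molecules at saturation.

    Returns the fit (with the seed recorded) and the depth/molecule curve.
    """
    reads = list(well_reads)
    if depths is None:
        depths = [int(v) for v in np.linspace(10_000, 150_000, 15)]
    depths = sorted(set(depths))
    if len(reads) < max(depths):
        usable = [dd for dd in depths if dd <= len(reads)]
        if len(usable) < len(depths):
            warnings.warn(
                f"well has {len(reads)} reads < max depth {max(depths)}; truncating grid"
            )
        depths = usable
    if len(depths) < 4:
        raise ValueError("need at least 4 usable subsampling depths")
    length = len(reads[0])
    codes = encode_umis(reads)
    rng = np.random.default_rng(seed)
    ys = []
    for depth in depths:
        sample = rng.choice(codes, size=depth, replace=False)
        ys.append(collapsed_unique_count(sample, length, d))
    fit = fit_asymptotic(depths, ys)
    fit.seed = seed
    curve = pd.DataFrame({"depth": depths, "molecules": ys})
    return fit, curve


def classify_wells(per_well_stats: pd.DataFrame) -> pd.Series:
    """Label wells as 'empty' or 'cell' from mapped-read composition.

    A well is empty iff its endogenous read fraction is < 0.20 and its
    spike-in read fraction is > 0.80 (both strict).  ``per_well_stats``
    carries either fraction columns (``endogenous_fraction``,
    ``spike_fraction``) or raw counts (``endogenous_reads``,
    ``spike_reads``) from which fractions are derived.
    """
    df = per_well_stats
    if "endogenous_fraction" in df.columns:
        endo = df["endogenous_fraction"].astype(float)
        spike = df["spike_fraction"].astype(float)
    else:
        total = df["endogenous_reads"] + df["spike_reads"]
        endo = df["endogenous_reads"] / total
        spike = df["spike_reads"] / total
    empty = (endo < 0.20) & (spike > 0.80)
    return pd.Series(np.where(empty, "empty", "cell"), index=df.index, name="label")


def predict_saturation(fit: SaturationFit, depth: float) -> tuple[float, float]:
    """Expected molecules at a sequencing depth and the saturation fraction.

    Returns (y(depth), y(depth)/asymptote); the fraction lies in [0, 1] for
    any non-negative depth when b1 >= 0.
    """
    y = float(fit.predict(depth))
    asym = fit.asymptote
    return y, (y / asym if asym != 0 else float("nan"))
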