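"""Calibration-curve fitting and LOD/LOQ estimation for PRM peptides.

Each peptide precursor is characterized on a dilution series (spiked
synthetic peptide amounts in fmol on column, plus blank injections). The
response model is a bilinear "hockey stick": a flat noise plateau up to a
changepoint concentration, then a linear response,

    I(c) = baseline                          for c <= changepoint
    I(c) = baseline + slope * (c - changepoint)  otherwise.

The limit of detection (LOD) is the smallest concentration whose mean fitted
intensity exceeds the upper bound of the blank predictive distribution (the
noise level); the limit of quantification (LOQ) is the smallest concentration
whose *lower* confidence bound of fitted intensity exceeds that same noise
bound. Both bounds are obtained by seeded nonparametric bootstrap, so a fit
is bit-reproducible given its inputs and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "ExclusionResult",
    "make_dilution_series",
    "exclude_saturated",
    "fit_calibration",
    "normalize_to_background",
    "calibrate_report",
    "BACKGROUND_PEPTIDE",
]

#: Background-matrix peptide (keratin 18) used as run-level normalization
#: scalar for calibration runs.
BACKGROUND_PEPTIDE = "QSVENDIHGLR"


@dataclass(frozen=True)
class CalibrationPoint:
    """One replicate response at one spiked concentration (0 = blank)."""

    peptide: str
    charge: int
    concentration: float
    replicate: int
    response: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.response < 0:
            raise ValueError("response must be >= 0")

    @property
    def is_blank(self) -> bool:
        return self.concentration == 0


@dataclass
class CalibrationFit:
    """Fitted bilinear response with bootstrap noise bound and LOD/LOQ.

    ``lod``/``loq`` are NaN and ``quantifiable`` is False when no crossing
    with the noise bound exists inside the fitted concentration range.
    ``boot_params`` holds the bootstrap (baseline, slope) pairs so confidence
    curves can be re-evaluated externally.
    """

    baseline: float
    changepoint: float
    slope: float
    noise_upper: float
    lod: float
    loq: float
    excluded_top: list[float] = field(default_factory=list)
    n_boot: int = 0
    ci_level: float = 0.95
    quantifiable: bool = True
    reason: str | None = None
    seed: int | None = None
    max_concentration: float = float("nan")
    boot_params: np.ndarray | None = field(default=None, repr=False)

    def predict(self, conc) -> np.ndarray:
        """Mean fitted intensity at concentration(s) ``conc``."""
        c = np.asarray(conc, dtype=float)
        return self.baseline + self.slope * np.maximum(0.0, c - self.changepoint)

    def predict_lower(self, conc) -> np.ndarray:
        """Lower bootstrap confidence bound of the fitted intensity."""
        if self.boot_params is None or len(self.boot_params) == 0:
            return self.predict(conc)
        c = np.atleast_1d(np.asarray(conc, dtype=float))
        x = np.maximum(0.0, c - self.changepoint)
        curves = self.boot_params[:, [0]] + self.boot_params[:, [1]] * x[None, :]
        out = np.quantile(curves, 1.0 - self.ci_level, axis=0)
        return out if np.ndim(conc) else float(out[0])


def make_dilution_series(top: float, fold: float, n_points: int) -> list[float]:
    """Concentrations of an ``n_points``-point ``fold``-fold serial dilution.

    Returns ``[top, top/fold, ..., top/fold**(n_points-1)]`` (descending).
    The assay's design is a 7-point 6-fold series from 1000 fmol, whose
    lowest point is 1000/6**6 ~= 0.021 fmol on column.
    """
    if top <= 0:
        raise ValueError("top concentration must be > 0")
    if fold <= 1:
        raise ValueError("dilution fold must be > 1")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return [top / fold**k for k in range(n_points)]


@dataclass
class ExclusionResult:
    points: list[CalibrationPoint]
    excluded: list[float]
    quantifiable: bool
    reason: str | None = None


def exclude_saturated(
    points: Sequence[CalibrationPoint],
    policy: str = "drop_top",
    *,
    tolerance: float = 0.20,
) -> ExclusionResult:
    """Remove the saturated top of a dilution series before fitting.

    ``policy="drop_top"`` unconditionally removes the highest concentration
    (the 1 pmol point routinely loses linearity and tails in the
    chromatogram). ``policy="lack_of_fit"`` removes the top concentration
    only if its mean response falls short of the linear extrapolation from
    the two preceding concentrations by more than ``tolerance`` (fraction).

    If fewer than 3 distinct concentrations remain the result is flagged
    not-quantifiable rather than raising.
    """
    nonblank = [p for p in points if not p.is_blank]
    concs = sorted({p.concentration for p in nonblank})
    if len(concs) < 2:
        raise ValueError("need at least 2 non-blank concentrations")

    def mean_at(c: float) -> float:
        vals = [p.response for p in nonblank if p.concentration == c]
        return float(np.mean(vals))

    excluded: list[float] = []
    if policy == "drop_top":
        excluded = [concs[-1]]
    elif policy == "lack_of_fit":
        if len(concs) >= 3:
            c1, c2, c3 = concs[-3], concs[-2], concs[-1]
            m1, m2 = mean_at(c1), mean_at(c2)
            expected = m2 + (m2 - m1) * (c3 - c2) / (c2 - c1)
            if expected > 0 and mean_at(c3) < (1.0 - tolerance) * expected:
                excluded = [concs[-1]]
    else:
        raise ValueError(f"unknown policy: {policy!r}")

    kept = [p for p in points if p.is_blank or p.concentration not in excluded]
    remaining = {p.concentration for p in kept if not p.is_blank}
    if len(remaining) < 3:
        return ExclusionResult(kept, excluded, False, "lt3_concentrations")
    return ExclusionResult(kept, excluded, True)


def _bilinear_ls(conc: np.ndarray, resp: np.ndarray, cp: float):
    """Least-squares (baseline, slope>=0) for a fixed changepoint; returns SSE."""
    x = np.maximum(0.0, conc - cp)
    if not np.any(x > 0):
        b, s = float(np.mean(resp)), 0.0
    else:
        A = np.column_stack([np.ones_like(conc), x])
        coef, *_ = np.linalg.lstsq(A, resp, rcond=None)
        b, s = float(coef[0]), float(coef[1])
        if s < 0:  # response must be non-decreasing
            b, s = float(np.mean(resp)), 0.0
    sse = float(np.sum((b + s * x - resp) ** 2))
    return b, s, sse


def _fit_changepoint(conc: np.ndarray, resp: np.ndarray, n_grid: int = 129):
    """Changepoint search on a log grid with golden-section refinement.

    Ties are broken toward the smaller changepoint (the grid is ascending and
    the first minimum wins).
    """
    cmin = float(np.min(conc[conc > 0]))
    cmax = float(np.max(conc))
    grid = np.geomspace(cmin / 50.0, cmax, n_grid)
    sses = np.array([_bilinear_ls(conc, resp, cp)[2] for cp in grid])
    i = int(np.argmin(sses))
    lo = math.log(grid[max(i - 1, 0)])
    hi = math.log(grid[min(i + 1, n_grid - 1)])
    # golden-section on log-changepoint
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _bilinear_ls(conc, resp, math.exp(c))[2]
    fd = _bilinear_ls(conc, resp, math.exp(d))[2]
    for _ in range(48):
        if fc <= fd:  # prefer the left (smaller) side on ties
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _bilinear_ls(conc, resp, math.exp(c))[2]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _bilinear_ls(conc, resp, math.exp(d))[2]
    cp = math.exp((a + b) / 2)
    if _bilinear_ls(conc, resp, grid[i])[2] < _bilinear_ls(conc, resp, cp)[2]:
        cp = float(grid[i])
    b0, s0, _ = _bilinear_ls(conc, resp, cp)
    return b0, cp, s0


def _first_crossing(
    func, grid: np.ndarray, threshold: float, refine_iter: int = 60
) -> float | None:
    """Smallest grid concentration where ``func(c) > threshold``, bisected."""
    vals = func(grid)
    above = vals > threshold
    if not above.any():
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(grid[0])
    lo, hi = float(grid[j - 1]), float(grid[j])
    for _ in range(refine_iter):
        mid = math.sqrt(lo * hi)
        if func(np.array([mid]))[0] > threshold:
            hi = mid
        else:
            lo = mid
    return hi


def fit_calibration(
    points: Sequence[CalibrationPoint],
    blanks: Iterable[float],
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
) -> CalibrationFit:
    """Fit the bilinear response and derive LOD/LOQ by seeded bootstrap.

    Parameters
    ----------
    points:
        Non-blank calibration points (blanks among them are routed to the
        blank pool automatically).
    blanks:
        Blank (0 fmol) responses; at least one required.
    n_boot:
        Bootstrap resamples for both the blank predictive bound and the
        response confidence band.
    ci_level:
        One-sided level for the noise upper bound and the response lower
        bound (default 95%).
    seed:
        Seed for all resampling; recorded in the returned fit.

    Notes
    -----
    The blank predictive distribution is built by resampling blank values
    with replacement and adding resampled baseline-region fit residuals; its
    ``ci_level`` percentile is the noise bound. The response confidence band
    resamples replicate responses within each concentration and refits
    (baseline, slope) with the changepoint held at the full-data estimate.
    A fit with zero slope, or with no crossing of the noise bound inside the
    fitted range, is flagged not-quantifiable (NaN LOD/LOQ) instead of
    raising.
    """
    nonblank = [p for p in points if not p.is_blank]
    blank_vals = np.asarray(
        list(blanks) + [p.response for p in points if p.is_blank], dtype=float
    )
    conc = np.array([p.concentration for p in nonblank], dtype=float)
    resp = np.array([p.response for p in nonblank], dtype=float)
    uniq = np.unique(conc)
    if len(uniq) < 3:
        raise ValueError("need at least 3 distinct non-blank concentrations")
    if len(blank_vals) < 1:
        raise ValueError("need at least 1 blank replicate")

    cmax = float(uniq.max())

    def not_quantifiable(reason, b=0.0, cp=0.0, s=0.0, nu=float("nan")):
        return CalibrationFit(
            baseline=b, changepoint=cp, slope=s, noise_upper=nu,
            lod=float("nan"), loq=float("nan"), n_boot=n_boot,
            ci_level=ci_level, quantifiable=False, reason=reason, seed=seed,
            max_concentration=cmax,
        )

    if np.ptp(resp) == 0 and np.ptp(blank_vals) == 0:
        return not_quantifiable("degenerate_flat", b=float(resp[0]))

    b0, cp, s0 = _fit_changepoint(conc, resp)
    if s0 <= 0:
        return not_quantifiable("zero_slope", b=b0, cp=cp)

    rng = np.random.default_rng(seed)
    fitted = b0 + s0 * np.maximum(0.0, conc - cp)
    resid = resp - fitted
    base_resid = resid[conc <= cp]
    if base_resid.size == 0:
        base_resid = resid

    # blank predictive distribution (index-based resampling keeps the
    # procedure equivariant under rescaling of all responses)
    bi = rng.integers(0, len(blank_vals), size=n_boot)
    ri = rng.integers(0, len(base_resid), size=n_boot)
    noise_draws = blank_vals[bi] + base_resid[ri]
    noise_upper = float(np.quantile(noise_draws, ci_level))

    # stratified bootstrap of the response curve, changepoint fixed
    groups = [np.flatnonzero(conc == c) for c in uniq]
    boot = np.empty((n_boot, 2))
    for k in range(n_boot):
        idx = np.concatenate([rng.choice(g, size=g.size) for g in groups])
        bb, bs, _ = _bilinear_ls(conc[idx], resp[idx], cp)
        boot[k] = (bb, bs)

    fit = CalibrationFit(
        baseline=b0, changepoint=cp, slope=s0, noise_upper=noise_upper,
        lod=float("nan"), loq=float("nan"), n_boot=n_boot, ci_level=ci_level,
        seed=seed, max_concentration=cmax, boot_params=boot,
    )

    cmin_pos = float(uniq.min())
    grid = np.geomspace(cmin_pos * 1e-3, cmax, 2048)
    lod = _first_crossing(fit.predict, grid, noise_upper)
    if lod is None:
        fit.quantifiable = False
        fit.reason = "no_lod_crossing"
        return fit
    loq = _first_crossing(lambda c: np.atleast_1d(fit.predict_lower(c)), grid, noise_upper)
    if loq is None:
        fit.quantifiable = False
        fit.reason = "no_loq_crossing"
        fit.lod = lod
        return fit
    fit.lod = lod
    fit.loq = max(loq, lod)  # the bounds imply lod <= loq; clamp numeric slack
    return fit


def normalize_to_background(
    records: pd.DataFrame, background_peptide: str = BACKGROUND_PEPTIDE
) -> pd.DataFrame:
    """Divide light areas by each run's background-peptide total area.

    Calibration runs are normalized on a peptide from the background matrix
    (keratin 18 ``QSVENDIHGLR``) to remove run-level intensity drift. If the
    background peptide is absent the input is returned unchanged with a
    warning. Background rows themselves are removed from the output.
    """
    is_bg = records["peptide"] == background_peptide
    if not is_bg.any():
        warnings.warn(
            f"background peptide {background_peptide} not found; "
            "responses left unnormalized"
        )
        return records.copy()
    light_bg = records[is_bg & (records["label"] == "light")]
    scale = light_bg.groupby("sample")["area"].sum()
    out = records[~is_bg].copy()
    factors = out["sample"].map(scale)
    if factors.isna().any() or (factors <= 0).any():
        missing = sorted(out.loc[factors.isna() | (factors <= 0), "sample"].unique())
        raise ValueError(f"no background signal for samples: {missing}")
    out["area"] = out["area"] / factors.to_numpy()
    return out


def calibrate_report(
    records: pd.DataFrame,
    concentrations: dict[str, float] | pd.Series | None = None,
    *,
    policy: str = "drop_top",
    n_boot: int = 500,
    ci_level: float = 0.95,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Run the full calibration workflow on a transition report.

    ``records`` is a transition-report frame (see :mod:`prmflux.io`); the
    spiked amount per sample comes from ``concentrations`` (sample -> fmol)
    or, when omitted, from a ``concentration_fmol`` column. Per precursor the
    light fragment areas are summed per run, normalized to the background
    peptide, the saturated top excluded per ``policy``, and the bilinear
    model fitted. Returns one row per (peptide, charge) with fit parameters,
    LOD/LOQ and flags.
    """
    rec = records[records["label"] == "light"].copy()
    if concentrations is None:
        if "concentration_fmol" not in records.columns:
            raise ValueError("concentrations map or concentration_fmol column required")
        conc_map = (
            records.groupby("sample")["concentration_fmol"].first().astype(float)
        )
    else:
        conc_map = pd.Series(dict(concentrations), dtype=float)
    if normalize:
        rec = normalize_to_background(records[records["label"] == "light"])
    rows = []
    for (peptide, charge), grp in rec.groupby(["peptide", "charge"], sort=True):
        per_run = grp.groupby("sample")["area"].sum()
        pts, blanks = [], []
        for rep, (sample, response) in enumerate(per_run.items()):
            if sample not in conc_map.index:
                raise ValueError(f"no spiked concentration for sample {sample!r}")
            c = float(conc_map[sample])
            if c == 0:
                blanks.append(float(response))
            else:
                pts.append(
                    CalibrationPoint(peptide, int(charge), c, rep, float(response))
                )
        excl = exclude_saturated(pts, policy=policy)
        row = {
            "peptide": peptide,
            "charge": int(charge),
            "excluded_top": ";".join(f"{c:g}" for c in excl.excluded),
        }
        if not excl.quantifiable:
            row.update(
                baseline=np.nan, changepoint=np.nan, slope=np.nan,
                noise_upper=np.nan, lod=np.nan, loq=np.nan,
                quantifiable=False, reason=excl.reason,
            )
        else:
            fit = fit_calibration(
                excl.points, blanks, n_boot=n_boot, ci_level=ci_level, seed=seed
            )
            row.update(
                baseline=fit.baseline, changepoint=fit.changepoint,
                slope=fit.slope, noise_upper=fit.noise_upper,
                lod=fit.lod, loq=fit.loq,
                quantifiable=fit.quantifiable, reason=fit.reason,
            )
        rows.append(row)
    return pd.DataFrame(rows)
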