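"""Precipitation-gradient profiles: MAP binning and candidate-curve fitting.

Valid pixels are grouped into fixed-width MAP bins (default 50 mm, anchored
at 0, half-open ``[lo, lo + width)``), the response is averaged per bin,
and the bin means are fitted against the bin midpoints.  The fitting rule:
an ordinary least-squares line first; if its slope is significant
(p <= 0.05) the line is kept, otherwise exponential ``a * exp(b x)``,
quadratic and cubic candidates are fitted and the highest R-squared
(``1 - SSE/SST``) wins, ties going to the model with fewer parameters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedProfile",
    "GradientFit",
    "PeakResult",
    "bin_by_map",
    "subset_by_rain_reduction",
    "fit_candidates",
    "select_fit",
    "peak_of_fit",
]

_N_PARAMS = {"linear": 2, "exponential": 2, "quadratic": 3, "cubic": 4}


@dataclass
class BinnedProfile:
    """Per-bin mean and spread of a response along the MAP axis."""

    bin_lo: np.ndarray
    bin_hi: np.ndarray
    bin_mid: np.ndarray
    n_pixels: np.ndarray
    mean_y: np.ndarray
    sd_y: np.ndarray
    response: str
    width: float
    n_total: int  # valid pixels that entered binning (before any n_min drop)

    @property
    def n_bins(self) -> int:
        return self.bin_mid.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_lo,
                "bin_hi": self.bin_hi,
                "bin_mid": self.bin_mid,
                "n": self.n_pixels,
                "mean": self.mean_y,
                "sd": self.sd_y,
            }
        )

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path


def bin_by_map(pixels: pd.DataFrame, response: str, width: float = 50.0,
               n_min: int = 10) -> BinnedProfile:
    """Bin valid pixels by ``map_mm`` and average ``response`` per bin.

    Bins are anchored at multiples of ``width`` from 0 and half-open.
    Bins with fewer than ``n_min`` pixels are dropped.  Pixels whose
    response is NaN are ignored.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    sub = pixels
    if "valid" in sub.columns:
        sub = sub[sub["valid"].astype(bool)]
    sub = sub.dropna(subset=["map_mm", response])
    if len(sub) == 0:
        raise ValueError("zero valid pixels to bin")
    idx = np.floor(sub["map_mm"].to_numpy() / width).astype(np.int64)
    y = sub[response].to_numpy()
    order = np.unique(idx)
    lo = order * width
    n = np.array([(idx == k).sum() for k in order])
    mean = np.array([y[idx == k].mean() for k in order])
    sd = np.array(
        [y[idx == k].std(ddof=1) if (idx == k).sum() > 1 else np.nan
         for k in order]
    )
    keep = n >= n_min
    return BinnedProfile(
        bin_lo=lo[keep],
        bin_hi=lo[keep] + width,
        bin_mid=lo[keep] + width / 2,
        n_pixels=n[keep],
        mean_y=mean[keep],
        sd_y=sd[keep],
        response=response,
        width=float(width),
        n_total=int(len(sub)),
    )


def subset_by_rain_reduction(pixels: pd.DataFrame, lo: float = 0.05,
                             hi: float = 0.10) -> pd.DataFrame:
    """Valid pixels whose rain reduction lies in the closed interval
    ``[lo, hi]`` — the "similar degree of rainfall reduction" subset."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    sub = pixels
    if "valid" in sub.columns:
        sub = sub[sub["valid"].astype(bool)]
    rr = sub["rain_reduction"]
    return sub[(rr >= lo) & (rr <= hi)]


@dataclass
class GradientFit:
    """One fitted candidate curve along the MAP gradient."""

    family: str
    coefficients: np.ndarray  # polynomial: ascending powers; exponential: (a, b)
    r2: float
    p_value: float            # overall-fit F (== slope t for the line); NaN for exponential
    ci_x: np.ndarray = dc_field(repr=False, default=None)
    ci_lo: np.ndarray = dc_field(repr=False, default=None)
    ci_hi: np.ndarray = dc_field(repr=False, default=None)
    selected: bool = False

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "exponential":
            a, b = self.coefficients
            return a * np.exp(b * x)
        return np.polynomial.polynomial.polyval(x, self.coefficients)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "coefficients": [float(c) for c in self.coefficients],
            "r2": float(self.r2),
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
            "selected": bool(self.selected),
        }
        if self.ci_x is not None:
            d["ci_band"] = {
                "x": [float(v) for v in self.ci_x],
                "lo": [float(v) for v in self.ci_lo],
                "hi": [float(v) for v in self.ci_hi],
            }
        return d


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else 1.0


def _fit_polynomial(x: np.ndarray, y: np.ndarray, degree: int,
                    ci_x: np.ndarray) -> GradientFit:
    family = {1: "linear", 2: "quadratic", 3: "cubic"}[degree]
    exog = np.column_stack([x ** k for k in range(degree + 1)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(y, exog).fit()
        pred = model.get_prediction(
            np.column_stack([ci_x ** k for k in range(degree + 1)])
        )
        band = pred.conf_int(alpha=0.05)
        fp = model.f_pvalue
    # a zero-residual (exact) fit makes the F statistic degenerate -> p = 0
    if not np.isfinite(fp):
        fp = 0.0 if model.ssr <= 1e-12 * max(1.0, model.centered_tss) else np.nan
    return GradientFit(
        family=family,
        coefficients=np.asarray(model.params, dtype=float),
        r2=_r2(y, model.fittedvalues),
        p_value=float(fp),
        ci_x=ci_x, ci_lo=band[:, 0], ci_hi=band[:, 1],
    )


def _fit_exponential(x: np.ndarray, y: np.ndarray, ci_x: np.ndarray,
                     n_boot: int = 1000, seed: int = 0) -> GradientFit | None:
    pos = y > 0
    if pos.sum() < 2:
        logger.warning("exponential candidate skipped: too few positive bin means")
        return None
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    p0 = (float(np.exp(intercept)), float(slope))

    def f(x, a, b):
        return a * np.exp(b * x)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(f, x, y, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError) as err:
        logger.warning("exponential candidate did not converge: %s", err)
        return None
    yhat = f(x, *popt)
    # 95% band for the fitted mean by parametric bootstrap on the residual
    # scale (the exponential has no exact analytic band)
    dof = max(len(x) - 2, 1)
    sigma = float(np.sqrt(np.sum((y - yhat) ** 2) / dof))
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_boot):
        yb = yhat + rng.normal(0.0, sigma, size=len(x))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pb, _ = curve_fit(f, x, yb, p0=popt, maxfev=2000)
            curves.append(f(ci_x, *pb))
        except (RuntimeError, ValueError):
            continue
    if curves:
        stack = np.vstack(curves)
        lo = np.percentile(stack, 2.5, axis=0)
        hi = np.percentile(stack, 97.5, axis=0)
        fitted = f(ci_x, *popt)
        lo, hi = np.minimum(lo, fitted), np.maximum(hi, fitted)
    else:
        lo = hi = f(ci_x, *popt)
    return GradientFit(
        family="exponential",
        coefficients=np.asarray(popt, dtype=float),
        r2=_r2(y, yhat),
        p_value=np.nan,
        ci_x=ci_x, ci_lo=lo, ci_hi=hi,
    )


def fit_candidates(profile: BinnedProfile, p_gate: float = 0.05,
                   seed: int = 0, ci_points: int = 200) -> list[GradientFit]:
    """Fit the candidate families to bin means and mark the selection.

    The line is accepted outright when its p-value passes the gate;
    otherwise all converged candidates compete on R-squared (ties broken
    toward fewer parameters).  Requires at least 5 retained bins.
    """
    if profile.n_bins < 5:
        raise ValueError(
            f"insufficient bins: {profile.n_bins} < 5 required for fitting"
        )
    x, y = profile.bin_mid.astype(float), profile.mean_y.astype(float)
    ci_x = np.linspace(x.min(), x.max(), ci_points)

    linear = _fit_polynomial(x, y, 1, ci_x)
    fits = [linear]
    if linear.p_value <= p_gate:
        linear.selected = True
        return fits

    exp_fit = _fit_exponential(x, y, ci_x, seed=seed)
    if exp_fit is not None:
        fits.append(exp_fit)
    fits.append(_fit_polynomial(x, y, 2, ci_x))
    fits.append(_fit_polynomial(x, y, 3, ci_x))

    # highest R^2 wins; near-exact ties (e.g. nested exact fits) go to the
    # model with fewer parameters
    best = max(fits, key=lambda f: (round(f.r2, 9), -f.n_params))
    best.selected = True
    return fits


def select_fit(fits: list[GradientFit]) -> GradientFit:
    chosen = [f for f in fits if f.selected]
    if len(chosen) != 1:
        raise ValueError("expected exactly one selected fit")
    return chosen[0]


@dataclass
class PeakResult:
    map_mm: float
    on_boundary: bool


def peak_of_fit(fit: GradientFit, domain: tuple[float, float]) -> PeakResult:
    """Argmax of a quadratic/cubic fit over a closed MAP interval.

    Uses the closed-form roots of the derivative, clipped to the domain;
    a maximum attained only at a domain endpoint is flagged as a boundary
    peak (the curve is monotone over the domain).
    """
    if fit.family not in {"quadratic", "cubic"}:
        raise ValueError(f"no interior peak for a {fit.family} fit")
    lo, hi = float(domain[0]), float(domain[1])
    if not lo < hi:
        raise ValueError("empty domain")
    deriv = np.polynomial.polynomial.polyder(fit.coefficients)
    roots = np.polynomial.polynomial.polyroots(deriv)
    interior = [
        float(r.real) for r in np.atleast_1d(roots)
        if abs(r.imag) < 1e-9 and lo < r.real < hi
    ]
    candidates = interior + [lo, hi]
    values = fit.predict(np.asarray(candidates))
    best = int(np.argmax(values))
    return PeakResult(
        map_mm=candidates[best],
        on_boundary=best >= len(interior),
    )


def write_fits_json(fits_by_name: dict[str, list[GradientFit] | None],
                    path: str | Path) -> Path:
    """Serialize candidate fits (grouped by response name) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {}
    for name, fits in fits_by_name.items():
        payload[name] = None if fits is None else [f.to_dict() for f in fits]
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
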