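"""Hill dose-response fitting for FRET (E/E0) and radioligand-binding
(B/B0) series.

The response model is the four-parameter Hill function

    R(c) = bottom + (top - bottom) / (1 + (c / IC50)^h)

fit on log10 concentration with a deterministic initialization (plateaus
from the extreme-concentration means, IC50 from the midpoint crossing,
h = 1).  A three-parameter variant fixes h = 1.  Binding counts are
first normalized against the no-drug DMSO control and the nonspecific-
binding level.  Non-monotone ("biphasic") series are detected and
reported rather than force-fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from functools import lru_cache

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseSeries",
    "HillFit",
    "normalize_binding",
    "fit_hill",
    "detect_biphasic",
]


@dataclass
class DoseResponseSeries:
    """Replicate responses versus concentration, with assay metadata.

    ``points`` is a long-format table with columns
    conc_um, replicate, response (responses normalized to DMSO = 1).
    """

    compound_id: str
    points: pd.DataFrame
    assay: str = "fret"
    isoform: str = "RyR1"
    redox: str = "GSSG"
    free_ca_nM: float = 30.0

    def validate(self) -> None:
        missing = {"conc_um", "replicate", "response"} - set(self.points.columns)
        if missing:
            raise ValueError(f"points table missing columns {sorted(missing)}")
        conc = self.points["conc_um"].to_numpy(dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(conc).size < 4:
            raise ValueError("need at least 4 distinct concentrations")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.points["conc_um"].unique())

    def mean_response(self) -> pd.Series:
        return self.points.groupby("conc_um")["response"].mean()


@dataclass
class HillFit:
    bottom: float
    top: float
    ic50: float
    hill: float
    stderr: dict = field(default_factory=dict)
    converged: bool = False
    residual_rss: float = float("nan")
    poorly_constrained: bool = False
    n_points: int = 0

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (conc / self.ic50) ** self.hill)


def normalize_binding(raw, dmso_control: float, nonspecific: float):
    """Normalize raw binding counts onto the DMSO(=1)/nonspecific(=0) scale.

    response = (raw - nonspecific) / (dmso_control - nonspecific).  The
    map is affine and order-preserving.
    """
    if not dmso_control > nonspecific:
        raise ValueError("dmso_control must exceed nonspecific binding")
    raw = np.asarray(raw, dtype=float)
    out = (raw - nonspecific) / (dmso_control - nonspecific)
    return float(out) if out.ndim == 0 else out


def _hill_logc(logc, bottom, top, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_hill(series: DoseResponseSeries, fix_hill: bool = False) -> HillFit:
    """Least-squares Hill fit on log10 concentration.

    Initialization is deterministic: ``top`` from the lowest-
    concentration mean, ``bottom`` from the highest, IC50 from the
    concentration where the mean response crosses the plateau midpoint,
    h = 1.  After fitting, parameters are canonicalized so that
    ``hill > 0`` and ``top`` is the low-concentration plateau... i.e. a
    negative fitted slope swaps the plateaus instead.

    Standard errors come from the fit covariance.  A converged fit whose
    relative IC50 standard error exceeds 1 is flagged
    ``poorly_constrained`` (typical of monotone data with no plateau).
    Non-convergence is flagged, not raised.
    """
    series.validate()
    pts = series.points
    conc = pts["conc_um"].to_numpy(dtype=float)
    resp = pts["response"].to_numpy(dtype=float)
    logc = np.log10(conc)

    means = series.mean_response()
    c_sorted = means.index.to_numpy(dtype=float)
    m_sorted = means.to_numpy(dtype=float)
    top0 = float(m_sorted[0])
    bottom0 = float(m_sorted[-1])
    mid = 0.5 * (top0 + bottom0)
    # midpoint-crossing concentration (first crossing of the mean curve)
    cross = np.nonzero(np.sign(m_sorted - mid)[:-1] != np.sign(m_sorted - mid)[1:])[0]
    if cross.size:
        i = cross[0]
        ic50_0 = float(np.sqrt(c_sorted[i] * c_sorted[i + 1]))
    else:
        ic50_0 = float(np.sqrt(c_sorted[0] * c_sorted[-1]))

    params = lmfit.Parameters()
    params.add("bottom", value=bottom0)
    params.add("top", value=top0)
    params.add("log_ic50", value=np.log10(ic50_0), min=np.log10(c_sorted[0]) - 3,
               max=np.log10(c_sorted[-1]) + 3)
    params.add("hill", value=1.0, vary=not fix_hill)

    def residual(p):
        return _hill_logc(logc, p["bottom"], p["top"], p["log_ic50"], p["hill"]) - resp

    result = lmfit.minimize(residual, params, method="leastsq")

    p = result.params
    bottom, top = float(p["bottom"].value), float(p["top"].value)
    hill = float(p["hill"].value)
    ic50 = float(10.0 ** p["log_ic50"].value)
    if hill < 0:  # canonical ordering: positive slope, swap plateaus
        bottom, top = top, bottom
        hill = -hill

    stderr = {}
    for name in ("bottom", "top", "hill"):
        se = p[name].stderr
        stderr[name] = float(se) if se is not None else float("nan")
    log_se = p["log_ic50"].stderr
    stderr["ic50"] = (
        float(ic50 * np.log(10.0) * log_se) if log_se is not None else float("nan")
    )

    rss = float(np.sum(np.asarray(result.residual) ** 2))
    rel_se = stderr["ic50"] / ic50 if np.isfinite(stderr["ic50"]) else np.inf
    return HillFit(
        bottom=bottom,
        top=top,
        ic50=ic50,
        hill=hill,
        stderr=stderr,
        converged=bool(result.success),
        residual_rss=rss,
        poorly_constrained=bool(rel_se > 1.0),
        n_points=int(resp.size),
    )


def _pava(y: np.ndarray, w: np.ndarray, increasing: bool = True) -> np.ndarray:
    """Weighted isotonic regression by pool-adjacent-violators."""
    if not increasing:
        return _pava(y[::-1], w[::-1], True)[::-1]
    level, weight, count = [], [], []
    for yi, wi in zip(y, w):
        level.append(float(yi))
        weight.append(float(wi))
        count.append(1)
        while len(level) > 1 and level[-2] > level[-1]:
            wtot = weight[-2] + weight[-1]
            level[-2] = (level[-2] * weight[-2] + level[-1] * weight[-1]) / wtot
            weight[-2] = wtot
            count[-2] += count[-1]
            del level[-1], weight[-1], count[-1]
    return np.repeat(level, count)


def _mono_rss(m: np.ndarray, w: np.ndarray) -> float:
    """Weighted RSS of the best monotone (either direction) fit to the means."""
    return min(
        float(np.sum(w * (m - _pava(m, w, True)) ** 2)),
        float(np.sum(w * (m - _pava(m, w, False)) ** 2)),
    )


def _updown_rss(m: np.ndarray, w: np.ndarray) -> float:
    """Best weighted RSS of a rise-then-fall (or fall-then-rise) shape over
    the concentration means, scanning all interior turning points."""
    n = m.size
    best = np.inf
    for flip in (False, True):
        mm = -m if flip else m
        for k in range(1, n - 1):
            left = _pava(mm[: k + 1], w[: k + 1], True)
            right = _pava(mm[k:], w[k:], False)
            rss = float(np.sum(w[: k + 1] * (mm[: k + 1] - left) ** 2)) + float(
                np.sum(w[k:] * (mm[k:] - right) ** 2)
            )
            best = min(best, rss)
    return best


@lru_cache(maxsize=32)
def _null_quantile(counts: tuple, alpha: float, n_sim: int = 500) -> float:
    """Null (constant-truth) quantile of the mono-vs-updown improvement
    statistic for a given replicate-count pattern.

    The statistic is scale-free under the null (means_i ~ N(c, s^2/n_i)),
    so the distribution depends only on the count pattern; it is
    estimated once by Monte Carlo with a fixed internal seed and cached.
    """
    w = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(20200204)
    vals = np.empty(n_sim)
    for i in range(n_sim):
        m = rng.standard_normal(w.size) / np.sqrt(w)
        vals[i] = _mono_rss(m, w) - _updown_rss(m, w)
    return float(np.quantile(vals, 1.0 - alpha))


def detect_biphasic(series: DoseResponseSeries, alpha: float = 0.05) -> dict:
    """Flag a non-monotone (rise-then-fall or fall-then-rise) dose response.

    Compares the lack-of-fit of the best monotone shape against the best
    two-segment (up-down) shape over the concentration means, in units of
    the replicate pure-error variance.  The decision threshold is the
    Monte-Carlo null quantile of that improvement statistic (the scan over
    turning points makes its null grow with the number of concentrations,
    so no fixed chi-square cut holds the specificity), giving an
    approximate ``alpha`` false-positive rate under monotone truth.
    Biphasic series should be reported, not force-fit with a single Hill
    curve.
    """
    series.validate()
    if series.concentrations.size < 6:
        raise ValueError("need at least 6 concentrations for biphasic detection")

    grp = series.points.groupby("conc_um")["response"]
    means = grp.mean().to_numpy(dtype=float)
    counts = grp.count().to_numpy(dtype=float)
    n_total = int(counts.sum())

    # pooled within-concentration (pure error) variance
    sse_within = float(((series.points["response"] - grp.transform("mean")) ** 2).sum())
    df_within = n_total - means.size
    if df_within <= 0 or sse_within == 0:
        sigma2 = np.finfo(float).tiny
    else:
        sigma2 = sse_within / df_within

    rss_mono = _mono_rss(means, counts)
    rss_ud = _updown_rss(means, counts)

    t_stat = (rss_mono - rss_ud) / sigma2
    threshold = _null_quantile(tuple(int(c) for c in counts), alpha)
    flag = bool(t_stat > threshold)
    return {
        "biphasic": flag,
        "statistic": float(t_stat),
        "threshold": float(threshold),
        "rss_monotone": rss_mono,
        "rss_updown": rss_ud,
        "pure_error_var": float(sigma2),
    }
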