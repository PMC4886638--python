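"""Weighted five-parameter-logistic (5PL) standard curves.

The 5PL maps concentration x (pg/ml) to fluorescence

    f(x) = bottom + (top - bottom) / (1 + (x / ec50)^(-hill))^asym

with ``hill > 0`` giving a strictly increasing curve, ``asym`` the asymmetry
exponent (``asym = 1`` reduces to the symmetric 4PL), ``f(0) = bottom`` and
``f(x) -> top`` as ``x -> inf``.  Its inverse maps fluorescence back to
concentration and is the censoring bottleneck of concentration analyses:
fluorescence outside ``(bottom, top)`` has no concentration image, and
fluorescence inside the asymptotes but outside the standards' observed span
is only reachable by extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

from .plate_data import PlateDataset, ValidationError


class FitError(RuntimeError):
    """The 5PL optimizer failed to converge; carries the best candidate."""

    def __init__(self, message, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics


@dataclass
class FivePLFit:
    """Fitted standard-curve parameters and derived quantities."""

    bottom: float
    top: float
    ec50: float
    hill: float
    asym: float
    weight_mode: str = "inverse_response_squared"
    standards_fl_range: tuple[float, float] | None = None
    lod_fl: float | None = None
    lod_conc: float | None = None
    recovery: dict = field(default_factory=dict)  # nominal conc -> back-calc/nominal
    rss: float | None = None

    def __post_init__(self):
        if not (self.bottom < self.top):
            raise ValueError("require bottom < top")
        if min(self.ec50, self.hill, self.asym) <= 0:
            raise ValueError("ec50, hill and asym must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FivePLFit":
        d = dict(d)
        if d.get("standards_fl_range") is not None:
            d["standards_fl_range"] = tuple(d["standards_fl_range"])
        return cls(**d)


def fivepl(conc, params: FivePLFit):
    """Evaluate the 5PL at concentration(s) ``conc`` (pg/ml, >= 0)."""
    x = np.asarray(conc, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    out = np.full(x.shape, params.bottom, dtype=float)
    pos = x > 0
    with np.errstate(over="ignore"):
        t = (x[pos] / params.ec50) ** (-params.hill)
        out[pos] = params.bottom + (params.top - params.bottom) / (1.0 + t) ** params.asym
    return float(out) if np.isscalar(conc) or np.ndim(conc) == 0 else out


def _inverse_core(fl, p: FivePLFit):
    """Inverse of the 5PL for fl strictly inside (bottom, top)."""
    ratio = (p.top - p.bottom) / (fl - p.bottom)
    t = ratio ** (1.0 / p.asym) - 1.0
    return p.ec50 * t ** (-1.0 / p.hill)


def inverse_5pl(fit: FivePLFit, fl: float) -> tuple[float | None, str]:
    """Map a fluorescence value to (concentration, censor status).

    Status is ``in_range`` when fl lies within the standards' observed
    fluorescence span, ``extrapolated`` when it is outside that span but
    strictly inside the curve asymptotes, and ``oor_low`` / ``oor_high``
    (concentration absent) at or beyond the asymptotes.
    """
    if not np.isfinite(fl) or fl <= fit.bottom:
        return None, "oor_low"
    if fl >= fit.top:
        return None, "oor_high"
    conc = _inverse_core(fl, fit)
    if fit.standards_fl_range is not None:
        lo, hi = fit.standards_fl_range
        if lo <= fl <= hi:
            return conc, "in_range"
        return conc, "extrapolated"
    return conc, "in_range"


def _fivepl_raw(x, bottom, top, ec50, hill, asym):
    with np.errstate(over="ignore", divide="ignore"):
        t = np.where(x > 0, (np.maximum(x, 1e-300) / ec50) ** (-hill), np.inf)
        return bottom + (top - bottom) / (1.0 + t) ** asym


def fit_5pl(standards, weight_mode: str = "inverse_response_squared",
            max_restarts: int = 6) -> FivePLFit:
    """Fit a weighted 5PL to standard-curve points.

    Parameters
    ----------
    standards : sequence of (conc, fluorescence)
        Replicate points allowed; >= 5 distinct positive concentrations
        required.
    weight_mode : {"none", "inverse_response_squared", "replicate_variance"}
        ``inverse_response_squared`` (default) weights residuals by 1/f^2,
        the CV-constant error model typical of bead immunoassays;
        ``replicate_variance`` weights each level by the inverse replicate
        variance of its fluorescence.

    Notes
    -----
    The optimizer is multi-start local least squares with ec50, hill and
    asym log-parameterized, started from a symmetric (asym = 1) 4PL fit;
    convergence tolerance 1e-10 on the relative reduction of the weighted
    RSS.  The 5PL is ill-conditioned for extreme asymmetry, hence the
    restarts over a grid of asym seeds.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("standards must be (conc, fluorescence) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be strictly positive")
    levels = np.unique(x)
    if len(levels) < 5:
        raise ValueError("need >= 5 distinct concentration levels")

    if weight_mode == "none":
        w = np.ones_like(y)
    elif weight_mode == "inverse_response_squared":
        w = 1.0 / np.maximum(y, 1e-12)
    elif weight_mode == "replicate_variance":
        w = np.empty_like(y)
        for lv in levels:
            m = x == lv
            v = np.var(y[m], ddof=1) if m.sum() > 1 else np.nan
            w[m] = v
        fallback = np.nanmedian(w)
        w = np.where(np.isfinite(w) & (w > 0), w, max(fallback, 1e-12))
        w = 1.0 / np.sqrt(w)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    span = y.max() - y.min()
    b0 = y.min() - 0.05 * span
    t0 = y.max() + 0.05 * span
    ec0 = math.sqrt(levels.min() * levels.max())

    def residuals(theta):
        bottom, top_excess, lec, lhill, lasym = theta
        top = bottom + math.exp(top_excess)
        f = _fivepl_raw(x, bottom, top, math.exp(lec), math.exp(lhill),
                        math.exp(lasym))
        return w * (f - y)

    def run(theta0):
        return least_squares(residuals, theta0, method="lm",
                             xtol=1e-12, ftol=1e-10, gtol=1e-12,
                             max_nfev=20000)

    # 4PL warm start (asym frozen at 1), then 5PL restarts over asym seeds
    def residuals4(theta):
        bottom, top_excess, lec, lhill = theta
        top = bottom + math.exp(top_excess)
        f = _fivepl_raw(x, bottom, top, math.exp(lec), math.exp(lhill), 1.0)
        return w * (f - y)

    try:
        r4 = least_squares(residuals4,
                           [b0, math.log(max(t0 - b0, 1e-6)), math.log(ec0), 0.0],
                           method="lm", xtol=1e-12, ftol=1e-10, max_nfev=20000)
        base = list(r4.x)
    except Exception:
        base = [b0, math.log(max(t0 - b0, 1e-6)), math.log(ec0), 0.0]

    asym_seeds = [1.0, 0.5, 2.0, 0.25, 4.0, 0.8][:max_restarts]
    best = None
    for a0 in asym_seeds:
        try:
            res = run(base + [math.log(a0)])
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-20 * max(1.0, float(np.sum((w * y) ** 2))):
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("5PL fit did not converge",
                       best=None, diagnostics={"n_points": len(x)})

    bottom, top_excess, lec, lhill, lasym = best.x
    fit = FivePLFit(
        bottom=float(bottom),
        top=float(bottom + math.exp(top_excess)),
        ec50=float(math.exp(lec)),
        hill=float(math.exp(lhill)),
        asym=float(math.exp(lasym)),
        weight_mode=weight_mode,
        standards_fl_range=(float(y.min()), float(y.max())),
        rss=float(2 * best.cost),
    )
    # per-standard recovery: back-calculated / nominal concentration
    recovery = {}
    for lv in levels:
        fl_mean = float(y[x == lv].mean())
        conc, status = inverse_5pl(fit, fl_mean)
        recovery[float(lv)] = float(conc / lv) if conc is not None else float("nan")
    fit.recovery = recovery
    return fit


def lod_from_blanks(fit: FivePLFit, blank_fl, k: float = 2.0):
    """Detection limit from blank wells: mean + k standard deviations.

    Returns ``(lod_fl, lod_conc)``; ``lod_conc`` is None when the
    fluorescence limit falls below the curve bottom (status oor_low).
    """
    b = np.asarray(blank_fl, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 blank readings")
    lod_fl = float(b.mean() + k * b.std(ddof=1))
    conc, _ = inverse_5pl(fit, lod_fl)
    return lod_fl, conc


def map_dataset(ds: PlateDataset, fits: dict) -> PlateDataset:
    """Fill concentration and censor status on every sample well.

    ``fits`` maps ``(analyte, plate)`` to a :class:`FivePLFit`.  The
    fluorescence column is never altered; the fluorescence analysis path
    simply ignores ``censor_status``, so no record is ever lost there.
    """
    out = ds.df.copy()
    mask = out["well_role"] == "sample"
    need = out.loc[mask, ["analyte", "plate"]].drop_duplicates()
    missing = [t for t in need.itertuples(index=False) if (t.analyte, t.plate) not in fits]
    if missing:
        raise ValidationError(
            "no standard-curve fit for: "
            + ", ".join(f"({a}, {p})" for a, p in missing[:10])
        )
    conc = np.full(len(out), np.nan)
    status = np.array(out["censor_status"], dtype=object)
    key = out["analyte"].astype(str) + "||" + out["plate"].astype(str)
    for (analyte, plate), fit in fits.items():
        m = (mask & (key == f"{analyte}||{plate}")).to_numpy()
        if not m.any():
            continue
        fl = out.loc[m, "fluorescence"].to_numpy(dtype=float)
        low = fl <= fit.bottom
        high = fl >= fit.top
        ok = ~(low | high)
        c = np.full(fl.shape, np.nan)
        c[ok] = _inverse_core(fl[ok], fit)
        s = np.empty(fl.shape, dtype=object)
        s[low], s[high] = "oor_low", "oor_high"
        if fit.standards_fl_range is not None:
            lo, hi = fit.standards_fl_range
            s[ok] = np.where((fl[ok] >= lo) & (fl[ok] <= hi),
                             "in_range", "extrapolated")
        else:
            s[ok] = "in_range"
        conc[m] = c
        status[m] = s
    out.loc[mask, "concentration"] = conc[mask.to_numpy()]
    out["censor_status"] = status
    return PlateDataset(out, ds.log_base)
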