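"""Retention-time calibration on the iRT scale.

Two distinct fits live here.  First, observed chromatographic retention
times (seconds) are mapped to the dimensionless iRT scale via a small set
of anchor peptides with known iRT values (least-squares line, one
outlier-rejection pass).  Second, predicted iRT values (from any RT
predictor) are calibrated onto the observed iRT scale using a random
quarter of the calibration-library targets, with the remainder held out to
estimate the residual MAD.  The calibration family is monotone piecewise
linear on quantile knots (a plain line is available); calibrated values
then replace the native predictions in the library (the ``_RT`` variant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .libio import SpectralLibrary, copy_record


@dataclass
class IrtAnchorSet:
    """Anchor peptides with known iRT and their observed RT (seconds)."""

    peptides: list[str]
    known_irt: np.ndarray
    observed_rt: np.ndarray

    def __post_init__(self) -> None:
        self.known_irt = np.asarray(self.known_irt, dtype=float)
        self.observed_rt = np.asarray(self.observed_rt, dtype=float)
        if len(self.known_irt) < 2:
            raise ValueError("need at least 2 anchors")


#: published iRT values of the 11-peptide commercial iRT kit
IRT_KIT = {
    "LGGNEQVTR": -24.92, "GAGSSEPVTGLDAK": 0.00, "VEATFGVDESNAK": 12.39,
    "YILAGVENSK": 19.79, "TPVISGGPYEYR": 28.71, "TPVITGAPYEYR": 33.38,
    "DGLDAASYYAPVR": 42.26, "ADVTPADFSEWSK": 54.62, "GTFIIDPGGVIR": 70.52,
    "GTFIIDPAAVIR": 87.23, "LFLQFGAQGSPFLK": 116.79,
}


@dataclass
class LinearMap:
    slope: float
    intercept: float
    r_squared: float = float("nan")

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_rt_to_irt(anchors: IrtAnchorSet, outlier_z: float = 3.0) -> LinearMap:
    """Least-squares line irt = a*rt + b from anchor peptides.

    Anchors with internally studentized residual above ``outlier_z`` are
    dropped once and the line refitted.
    """
    rt, irt = anchors.observed_rt, anchors.known_irt
    if len(np.unique(rt)) < 2:
        raise ValueError("need at least 2 anchors with distinct RT")

    def _fit(x, y):
        a, b = np.polyfit(x, y, 1)
        resid = y - (a * x + b)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return a, b, resid, r2

    a, b, resid, r2 = _fit(rt, irt)
    n = len(rt)
    if n > 4:
        # externally studentized residuals: a gross outlier inflates the
        # pooled residual scale and masks itself under internal
        # studentization, so each point is judged against the fit without it
        h = 1.0 / n + (rt - rt.mean()) ** 2 / ((rt - rt.mean()) ** 2).sum()
        s2 = float(resid @ resid) / (n - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2_del = ((n - 2) * s2 - resid ** 2 / (1 - h)) / (n - 3)
            t = resid / np.sqrt(np.maximum(s2_del, 0) * (1 - h))
        keep = ~(np.abs(t) > outlier_z)
        if keep.sum() >= 2 and not keep.all():
            a, b, _, r2 = _fit(rt[keep], irt[keep])
    return LinearMap(slope=float(a), intercept=float(b), r_squared=float(r2))


@dataclass
class RtCalibrationModel:
    """Monotone map from predicted iRT to the observed iRT scale.

    ``kind='linear'`` stores two coefficients; ``kind='piecewise_linear'``
    stores quantile knots with monotone node values and extrapolates
    linearly beyond the outermost knots.
    """

    kind: str
    knots_x: np.ndarray
    knots_y: np.ndarray
    residual_mad: float = float("nan")

    def __post_init__(self) -> None:
        self.knots_x = np.asarray(self.knots_x, dtype=float)
        self.knots_y = np.asarray(self.knots_y, dtype=float)
        if np.any(np.diff(self.knots_x) <= 0) or np.any(np.diff(self.knots_y) < 0):
            raise ValueError("calibration model must be monotone increasing")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        kx, ky = self.knots_x, self.knots_y
        y = np.interp(x, kx, ky)
        # linear extrapolation with the edge-segment slopes
        if len(kx) >= 2:
            lo = x < kx[0]
            hi = x > kx[-1]
            s0 = (ky[1] - ky[0]) / (kx[1] - kx[0])
            s1 = (ky[-1] - ky[-2]) / (kx[-1] - kx[-2])
            y = np.where(lo, ky[0] + s0 * (x - kx[0]), y)
            y = np.where(hi, ky[-1] + s1 * (x - kx[-1]), y)
        return y if y.ndim else float(y)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "knots_x": self.knots_x.tolist(),
                       "knots_y": self.knots_y.tolist(),
                       "residual_mad": self.residual_mad}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RtCalibrationModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(kind=obj["kind"], knots_x=obj["knots_x"],
                   knots_y=obj["knots_y"], residual_mad=obj["residual_mad"])


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares monotone nondecreasing fit."""
    y = y.astype(float).copy()
    n = len(y)
    w = np.ones(n)
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / (wts[i] + wts[i + 1])
            wts[i] += wts[i + 1]
            vals[i] = merged
            del vals[i + 1], wts[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = []
    for v, wt in zip(vals, wts):
        out.extend([v] * int(wt))
    return np.array(out)


def fit_calibration(predicted_irt: Sequence[float],
                    observed_irt: Sequence[float],
                    frac: float = 0.25,
                    kind: str = "piecewise_linear",
                    n_knots: int = 10,
                    seed: int = 1) -> RtCalibrationModel:
    """Fit predicted-iRT -> observed-iRT calibration on a ``frac`` subsample.

    The subsample is drawn uniformly at random (seeded, deterministic); the
    unsampled remainder supplies the held-out residual MAD.  The piecewise
    family places knots at quantiles of the training predictions and
    enforces monotone node values by pooling adjacent violators.
    """
    x = np.asarray(predicted_irt, dtype=float)
    y = np.asarray(observed_irt, dtype=float)
    if len(x) != len(y):
        raise ValueError("predicted and observed must pair up")
    if len(x) < 10:
        raise ValueError("need at least 10 paired targets to calibrate")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(frac * len(x))))
    idx = rng.permutation(len(x))
    tr, ho = idx[:n_train], idx[n_train:]
    xt, yt = x[tr], y[tr]

    if kind == "linear" or len(np.unique(xt)) < 3:
        a, b = np.polyfit(xt, yt, 1)
        if a <= 0:
            raise ValueError("fitted calibration is not increasing")
        x0, x1 = float(xt.min()), float(xt.max())
        model = RtCalibrationModel(kind="linear",
                                   knots_x=[x0, x1],
                                   knots_y=[a * x0 + b, a * x1 + b])
    elif kind == "piecewise_linear":
        qs = np.linspace(0, 1, n_knots)
        kx = np.quantile(xt, qs)
        kx, uniq = np.unique(kx, return_index=True)
        # node value = local mean of a linear fit within each segment; use
        # interpolation of a smoothed empirical relation: bin targets by
        # nearest knot and average, then repair monotonicity.
        order = np.argsort(xt)
        xs, ys = xt[order], yt[order]
        ky = np.empty(len(kx))
        for i, k in enumerate(kx):
            lo = kx[i - 1] if i > 0 else -np.inf
            hi = kx[i + 1] if i < len(kx) - 1 else np.inf
            m = (xs >= (k + lo) / 2 if np.isfinite(lo) else xs >= -np.inf) & \
                (xs <= (k + hi) / 2 if np.isfinite(hi) else xs <= np.inf)
            ky[i] = ys[m].mean() if m.any() else np.interp(k, xs, ys)
        ky = _pava_increasing(ky)
        # strictly increasing x already ensured by unique(); flat y is allowed
        if np.all(np.diff(ky) == 0):
            raise ValueError("calibration degenerate: flat fit after repair")
        model = RtCalibrationModel(kind="piecewise_linear", knots_x=kx, knots_y=ky)
    else:
        raise ValueError(f"unknown calibration kind {kind!r}")

    holdout = (x[ho], y[ho]) if len(ho) else (xt, yt)
    resid = holdout[1] - model(holdout[0])
    model.residual_mad = float(np.median(np.abs(resid - np.median(resid))))
    return model


def apply_rt(lib: SpectralLibrary, model: RtCalibrationModel) -> SpectralLibrary:
    """Replace every record's iRT with the calibrated value (``_RT``)."""
    out = lib.with_records(
        copy_record(rec, irt=float(model(rec.irt))) for rec in lib)
    out.tag("_RT")
    return out
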