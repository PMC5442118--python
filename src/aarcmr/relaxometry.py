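"""Pixel-wise T2 and Look-Locker T1 relaxometry.

T2 maps come from bounded nonlinear least squares of the mono-exponential
decay S(TE) = S0 exp(-TE/T2), initialized from a signal-weighted log-linear
regression.  T1 maps come from the 3-parameter Look-Locker model
s(t) = A - B exp(-t/T1*) fitted after polarity restoration of magnitude
inversion-recovery data, followed by the classical apparent-to-true
correction T1 = T1* (B/A - 1).

All map-level fitting runs through one vectorized Levenberg-Marquardt engine
(pixels fitted in parallel as a batch); the single-pixel entry points call
the same engine with a batch of one, so pixel and map results agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import ParameterMap, SliceStack

log = logging.getLogger(__name__)


@dataclass
class FitOptions:
    """Nonlinear-fit configuration shared by the T2 and Look-Locker models.

    Bounds: T2 in [1, 300] ms, T1* in [0.05, 5] s, amplitudes in
    (0, 10 x max signal] (scaled per pixel).  Pixels are flagged invalid when
    the fit fails to converge, sits at a bound, or r^2 < min_r2.
    """

    model: str = "monoexp_t2"  # or "look_locker_3param"
    t2_bounds_ms: tuple = (1.0, 300.0)
    t1_star_bounds_s: tuple = (0.05, 5.0)
    amplitude_factor: float = 10.0  # upper amplitude bound = factor * max|signal|
    max_iter: int = 60
    tol: float = 1e-10
    polarity_restoration: bool = True
    # r^2 is scale-dependent (slower decay over a fixed TE range explains less
    # variance at the same SNR), so an aggressive cut would preferentially
    # discard long-T2 edema pixels; 0.5 only rejects genuinely broken fits.
    min_r2: float = 0.5

    def __post_init__(self):
        for lo, hi in (self.t2_bounds_ms, self.t1_star_bounds_s):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")


# ---------------------------------------------------------------------------
# vectorized Levenberg-Marquardt
# ---------------------------------------------------------------------------

def _lm_batch(model_jac, y, p0, lower, upper, max_iter=60, tol=1e-10):
    """Batched bounded Levenberg-Marquardt for small parameter counts.

    model_jac(p) -> (yhat [n, t], J [n, t, k]); parameters are clipped to the
    box after every accepted step.  Returns (p, sse, converged, at_bounds).
    """
    p = np.clip(p0.astype(float), lower, upper)
    n, k = p.shape
    lam = np.full(n, 1e-3)
    yhat, jac = model_jac(p)
    r = y - yhat
    sse = np.einsum("nt,nt->n", r, r)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        ja = jac[active]
        ra = r[active]
        jtj = np.einsum("ntk,ntl->nkl", ja, ja)
        jtr = np.einsum("ntk,nt->nk", ja, ra)
        diag = np.einsum("nkk->nk", jtj)
        damp = lam[active][:, None] * np.maximum(diag, 1e-12)
        aug = jtj + damp[:, :, None] * np.eye(k)[None]
        try:
            step = np.linalg.solve(aug, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            aug = aug + 1e-9 * np.eye(k)[None]
            step = np.linalg.solve(aug, jtr[..., None])[..., 0]
        p_try_full = p.copy()
        p_try_full[active] = np.clip(p[active] + step, lower[active], upper[active])
        yhat_try, jac_try = model_jac(p_try_full)
        r_try = y - yhat_try
        sse_try = np.einsum("nt,nt->n", r_try, r_try)
        better = sse_try < sse
        accept = better & active
        # relative improvement small -> converged
        improved = np.zeros(n, dtype=bool)
        improved[accept] = (sse[accept] - sse_try[accept]) <= tol * (sse[accept] + 1e-30)
        p[accept] = p_try_full[accept]
        r[accept] = r_try[accept]
        yhat[accept] = yhat_try[accept]
        jac[accept] = jac_try[accept]
        sse[accept] = sse_try[accept]
        lam[accept] = np.maximum(lam[accept] * 0.3, 1e-12)
        reject = active & ~better
        lam[reject] *= 10.0
        converged |= improved
        converged |= lam > 1e10  # stuck: cannot improve further
    at_bounds = np.any((p <= lower + 1e-12) | (p >= upper - 1e-12), axis=1)
    return p, sse, converged | (lam > 1e10), at_bounds


def _r2(y, sse):
    sst = np.einsum("nt,nt->n", y - y.mean(axis=1, keepdims=True),
                    y - y.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sst > 0, 1.0 - sse / sst, 0.0)


# ---------------------------------------------------------------------------
# T2: S(TE) = S0 exp(-TE / T2)
# ---------------------------------------------------------------------------

def _fit_t2_batch(signals: np.ndarray, te_ms: np.ndarray, options: FitOptions):
    """Fit S0, T2 for a (n_pixels, n_echoes) batch.

    Returns (s0, t2_ms, sse, r2, valid).
    """
    y = np.asarray(signals, dtype=float)
    te = np.asarray(te_ms, dtype=float)
    n = y.shape[0]
    lo_t2, hi_t2 = options.t2_bounds_ms
    smax = np.maximum(np.abs(y).max(axis=1), 1e-12)
    lower = np.column_stack([np.full(n, 1e-9), np.full(n, lo_t2)])
    upper = np.column_stack([options.amplitude_factor * smax, np.full(n, hi_t2)])

    # log-linear init, weighted by signal to de-emphasize the noisy tail
    ypos = np.maximum(y, 1e-9)
    w = ypos**2
    lny = np.log(ypos)
    sw = w.sum(axis=1)
    mx = (w * te).sum(axis=1) / sw
    my = (w * lny).sum(axis=1) / sw
    sxx = (w * (te - mx[:, None])**2).sum(axis=1)
    sxy = (w * (te - mx[:, None]) * (lny - my[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, -1.0 / 25.0)
    t2_init = np.where(slope < 0, -1.0 / np.minimum(slope, -1e-9), hi_t2)
    t2_init = np.clip(t2_init, lo_t2, hi_t2)
    s0_init = np.clip(np.exp(my - slope * mx), lower[:, 0], upper[:, 0])

    def model_jac(p):
        s0, t2 = p[:, 0], p[:, 1]
        e = np.exp(-te[None, :] / t2[:, None])
        yhat = s0[:, None] * e
        jac = np.stack([e, yhat * te[None, :] / (t2[:, None]**2)], axis=2)
        return yhat, jac

    p0 = np.column_stack([s0_init, t2_init])
    p, sse, conv, at_bounds = _lm_batch(model_jac, y, p0, lower, upper,
                                        options.max_iter, options.tol)
    r2 = _r2(y, sse)
    flat = y.max(axis=1) - y.min(axis=1) <= 0
    valid = conv & ~at_bounds & (r2 >= options.min_r2) & ~flat & (p[:, 1] > 0)
    return p[:, 0], p[:, 1], sse, r2, valid


def fit_t2_pixel(signal, te_list_ms, options: Optional[FitOptions] = None):
    """Least-squares (S0, T2) for one pixel's multi-echo decay.

    Returns (s0, t2_ms, diagnostics) with diagnostics carrying the residual
    sum of squares, r^2 and the validity flag.  All-zero or degenerate
    signals yield an invalid pixel, not an exception.
    """
    options = options or FitOptions(model="monoexp_t2")
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(te_list_ms, dtype=float)
    if signal.ndim != 1 or len(signal) != len(te):
        raise ValueError("signal and te_list_ms lengths differ")
    if len(te) < 3:
        raise ValueError("need at least 3 echoes for a T2 fit")
    s0, t2, sse, r2, valid = _fit_t2_batch(signal[None, :], te, options)
    diag = {"sse": float(sse[0]), "r2": float(r2[0]), "valid": bool(valid[0])}
    return float(s0[0]), float(t2[0]), diag


def fit_t2_map(stack: SliceStack, analysis_mask: np.ndarray,
               options: Optional[FitOptions] = None) -> ParameterMap:
    """Pixel-wise T2 map (ms) over the analysis mask."""
    options = options or FitOptions(model="monoexp_t2")
    if stack.meta.modality != "multi_echo_se":
        raise ValueError("fit_t2_map needs a multi_echo_se stack")
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != (stack.n_slices, *stack.spatial_shape):
        raise ValueError("analysis mask shape does not match stack")
    te = np.asarray(stack.meta.te_list_ms)
    values = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    r2map = np.full(mask.shape, np.nan)
    s0map = np.full(mask.shape, np.nan)
    idx = np.nonzero(mask)
    n_pix = len(idx[0])
    if n_pix == 0:
        log.warning("fit_t2_map: empty analysis mask")
        return ParameterMap(values, valid, "ms", {"r2": r2map, "s0": s0map, "n_invalid": 0})
    y = np.moveaxis(stack.data, 1, -1)[idx]  # (n_pix, n_echoes)
    s0, t2, sse, r2, ok = _fit_t2_batch(y.astype(float), te, options)
    values[idx] = t2
    valid[idx] = ok
    r2map[idx] = r2
    s0map[idx] = s0
    values[~valid] = np.nan
    n_invalid = int(n_pix - ok.sum())
    if n_invalid:
        log.info("fit_t2_map: %d/%d invalid pixels", n_invalid, n_pix)
    return ParameterMap(values, valid, "ms", {"r2": r2map, "s0": s0map, "n_invalid": n_invalid})


# ---------------------------------------------------------------------------
# Look-Locker T1
# ---------------------------------------------------------------------------

def _fit_ll_signed_batch(y: np.ndarray, ti: np.ndarray, options: FitOptions):
    """3-parameter (A, B, T1*) fit of already-signed recovery curves."""
    n = y.shape[0]
    lo_t, hi_t = options.t1_star_bounds_s
    smax = np.maximum(np.abs(y).max(axis=1), 1e-12)
    amp_hi = options.amplitude_factor * smax
    lower = np.column_stack([np.full(n, 1e-9), np.full(n, 1e-9), np.full(n, lo_t)])
    upper = np.column_stack([amp_hi, 2.5 * amp_hi, np.full(n, hi_t)])

    # init: A from the recovered tail, B from the inverted start, T1* from the
    # zero-crossing time (t_null = T1* ln(B/A))
    a0 = np.maximum(y[:, -3:].mean(axis=1), 1e-6)
    b0 = np.maximum(a0 + np.abs(y[:, 0]), 2e-6)
    i_min = np.argmin(np.abs(y), axis=1)
    t_null = ti[i_min]
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.clip(t_null / np.maximum(np.log(b0 / a0), 1e-3), lo_t, hi_t)

    def model_jac(p):
        a, b, t1s = p[:, 0], p[:, 1], p[:, 2]
        e = np.exp(-ti[None, :] / t1s[:, None])
        yhat = a[:, None] - b[:, None] * e
        jac = np.stack([np.ones_like(e), -e,
                        -b[:, None] * e * ti[None, :] / (t1s[:, None]**2)], axis=2)
        return yhat, jac

    p0 = np.column_stack([a0, b0, t0])
    p, sse, conv, at_bounds = _lm_batch(model_jac, y, p0, lower, upper,
                                        options.max_iter, options.tol)
    r2 = _r2(y, sse)
    flat = y.max(axis=1) - y.min(axis=1) <= 0
    valid = conv & ~at_bounds & (r2 >= options.min_r2) & ~flat
    return p, sse, r2, valid


def _polarity_candidates(y_abs: np.ndarray, max_candidates: Optional[int] = None):
    """Candidate flip indices for magnitude IR data: up to the minimum + 1."""
    i_min = int(np.argmin(y_abs))
    cand = list(range(0, i_min + 2))
    if max_candidates is not None and len(cand) > max_candidates:
        cand = cand[-max_candidates:]
    return [c for c in cand if c <= len(y_abs)]


def restore_polarity(signal, ti_list_s, options: Optional[FitOptions] = None):
    """Restore the sign of a magnitude inversion-recovery series.

    All samples before the candidate zero-crossing index are negated; the
    candidate (restricted to indices up to the series minimum + 1) minimizing
    the subsequent 3-parameter fit residual wins.  Monotone, already-positive
    recoveries come back unchanged.
    """
    options = options or FitOptions(model="look_locker_3param")
    y = np.asarray(signal, dtype=float)
    ti = np.asarray(ti_list_s, dtype=float)
    best = None
    for c in _polarity_candidates(np.abs(y)):
        ys = y.copy()
        ys[:c] = -np.abs(ys[:c])
        _, sse, _, _ = _fit_ll_signed_batch(ys[None, :], ti, options)
        if best is None or sse[0] < best[0]:
            best = (float(sse[0]), ys)
    return best[1]


def fit_ll_pixel(signal, ti_list_s, options: Optional[FitOptions] = None):
    """3-parameter Look-Locker fit (A, B, T1*) for one pixel.

    Magnitude data are polarity-restored first when the option is on.
    Returns (a, b, t1_star_s, diagnostics); degenerate flat series are
    flagged invalid.
    """
    options = options or FitOptions(model="look_locker_3param")
    y = np.asarray(signal, dtype=float)
    ti = np.asarray(ti_list_s, dtype=float)
    if y.ndim != 1 or len(y) != len(ti):
        raise ValueError("signal and ti_list_s lengths differ")
    if len(ti) < 5:
        raise ValueError("need at least 5 recovery samples")
    if options.polarity_restoration:
        y = restore_polarity(y, ti, options)
    p, sse, r2, valid = _fit_ll_signed_batch(y[None, :], ti, options)
    diag = {"sse": float(sse[0]), "r2": float(r2[0]), "valid": bool(valid[0])}
    return float(p[0, 0]), float(p[0, 1]), float(p[0, 2]), diag


def correct_t1(a, b, t1_star_s):
    """Classical Look-Locker correction T1 = T1* (B/A - 1).

    Element-wise; returns NaN where the parameters are unphysical
    (A <= 0 or B <= A, which would imply a non-positive T1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t1_star = np.asarray(t1_star_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = t1_star * (b / a - 1.0)
    bad = (a <= 0) | (b <= a) | (t1_star <= 0)
    t1 = np.where(bad, np.nan, t1)
    if t1.ndim == 0:
        return float(t1)
    return t1


def fit_t1_map(stack: SliceStack, analysis_mask: np.ndarray,
               options: Optional[FitOptions] = None) -> ParameterMap:
    """Pixel-wise corrected T1 map (s) from a Look-Locker IR stack.

    For magnitude stacks each pixel is fitted for the polarity candidates
    (series minimum and minimum + 1) and the lower-residual restoration
    wins; the apparent T1* is then corrected to true T1.
    """
    options = options or FitOptions(model="look_locker_3param")
    if stack.meta.modality != "look_locker_ir":
        raise ValueError("fit_t1_map needs a look_locker_ir stack")
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != (stack.n_slices, *stack.spatial_shape):
        raise ValueError("analysis mask shape does not match stack")
    ti = np.asarray(stack.meta.ti_list_s)
    shape = mask.shape
    values = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    diags = {k: np.full(shape, np.nan) for k in ("a", "b", "t1_star", "r2")}
    idx = np.nonzero(mask)
    n_pix = len(idx[0])
    if n_pix == 0:
        log.warning("fit_t1_map: empty analysis mask")
        diags["n_invalid"] = 0
        return ParameterMap(values, valid, "s", diags)
    y = np.moveaxis(stack.data, 1, -1)[idx].astype(float)

    if options.polarity_restoration and stack.meta.magnitude:
        i_min = np.argmin(np.abs(y), axis=1)
        best = None
        for off in (0, 1):
            c = np.minimum(i_min + off, y.shape[1])
            ys = y.copy()
            flip = np.arange(y.shape[1])[None, :] < c[:, None]
            ys = np.where(flip, -np.abs(ys), ys)
            p_c, sse_c, r2_c, valid_c = _fit_ll_signed_batch(ys, ti, options)
            if best is None:
                best = [p_c, sse_c, r2_c, valid_c]
            else:
                take = sse_c < best[1]
                for arr, new in zip(best, (p_c, sse_c, r2_c, valid_c)):
                    arr[take] = new[take]
        p, sse, r2, ok = best
    else:
        p, sse, r2, ok = _fit_ll_signed_batch(y, ti, options)

    t1 = correct_t1(p[:, 0], p[:, 1], p[:, 2])
    ok = ok & np.isfinite(t1) & (np.asarray(t1) > 0)
    values[idx] = t1
    valid[idx] = ok
    values[~valid] = np.nan
    for name, col in zip(("a", "b", "t1_star", "r2"),
                         (p[:, 0], p[:, 1], p[:, 2], r2)):
        diags[name][idx] = col
    n_invalid = int(n_pix - ok.sum())
    if n_invalid:
        log.info("fit_t1_map: %d/%d invalid pixels", n_invalid, n_pix)
    diags["n_invalid"] = n_invalid
    return ParameterMap(values, valid, "s", diags)
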