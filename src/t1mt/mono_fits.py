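"""Per-method mono-exponential T1 estimation procedures.

Each T1-mapping family publishes its own fitting recipe; applying those
recipes to signals simulated with a two-pool MT model is what turns one
tissue into many different "T1" values.  The fitters here mirror the standard
procedures:

* inversion recovery — either the saturation-prepared model
  ``s(TD, TI) = M0 (1 - (1 + eps (1 - e^{-TD/T1})) e^{-TI/T1})``
  with inversion efficiency ``eps`` (used when the protocol records its
  saturation-recovery delays), or the classic three-parameter model
  ``s(TI) = a + b e^{-TI/T1}``;
* saturation recovery — ``M0 (1 - e^{-t/T1})``;
* Look-Locker — ``A - B e^{-t/T1*}`` along the readout train followed by the
  correction ``T1 = T1* (B/A - 1)``;
* variable flip angle — the DESPOT1 linearization: regress
  ``s/sin(b1 a)`` on ``s/tan(b1 a)``; the slope is ``exp(-TR/T1)``;
* MP2RAGE — the bounded uniform contrast ``UNI = s1 s2 / (s1^2 + s2^2)``
  inverted through a dictionary built by simulating the same protocol under
  the mono-exponential model over a fine T1 grid.

Nonlinear fits are seeded by a coarse variable-projection grid search over T1
(the nuisance amplitudes are profiled out linearly) and polished with bounded
least squares; T1 is constrained to [0.05, 10] s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .sequences import SequenceProtocol, SimulatedSignal, mono_signal_t1_grid

__all__ = [
    "T1Estimate",
    "FitError",
    "fit_ir",
    "fit_sr",
    "fit_ll",
    "fit_vfa",
    "mp2rage_t1",
    "dispatch_fit",
    "FIT_PROCEDURES",
]

T1_BOUNDS = (0.05, 10.0)
_T1_SEED_GRID = np.geomspace(T1_BOUNDS[0], T1_BOUNDS[1], 60)


class FitError(RuntimeError):
    """Raised when a fitting procedure cannot produce a T1 estimate."""


@dataclass
class T1Estimate:
    """A method-specific T1 value with its nuisance parameters and
    diagnostics (always populated, also on questionable fits)."""

    t1: float
    aux: dict = field(default_factory=dict)
    residual_norm: float = np.inf
    converged: bool = False
    message: str = ""


def _polish(residual_fn, x0, bounds, jac="2-point"):
    res = least_squares(
        residual_fn, x0, bounds=bounds, jac=jac, xtol=1e-12, ftol=1e-12,
        gtol=1e-10, max_nfev=200,
    )
    return res


# ----------------------------------------------------------------------------
# inversion recovery
# ----------------------------------------------------------------------------


def _ir_basis(ti, td, t1_grid, eps_grid):
    """Model shapes over the (T1, eps) seed grid, shape (nT1, nEps, n)."""
    e_ti = np.exp(-ti[None, :] / t1_grid[:, None])  # (nT1, n)
    sat = 1.0 - np.exp(-td[None, :] / t1_grid[:, None])
    return 1.0 - (
        (1.0 + eps_grid[None, :, None] * sat[:, None, :]) * e_ti[:, None, :]
    )


def _fit_ir_signed(ti, s, td=None):
    """Signed IR fit; returns (t1, aux, rnorm, converged)."""
    ti = np.asarray(ti, float)
    s = np.asarray(s, float)
    if td is None:
        # s = a + b exp(-ti/t1); profile (a, b) over a T1 grid (closed-form
        # 2x2 normal equations, vectorized over the grid)
        E = np.exp(-ti[None, :] / _T1_SEED_GRID[:, None])
        n = ti.size
        se = E.sum(axis=1)
        see = (E * E).sum(axis=1)
        sy = s.sum()
        sey = E @ s
        det = n * see - se**2
        det = np.where(det <= 0, np.nan, det)
        b = (n * sey - se * sy) / det
        a = (sy - b * se) / n
        rss = ((a[:, None] + b[:, None] * E - s) ** 2).sum(axis=1)
        k = int(np.nanargmin(rss))
        t1_0, a0, b0 = _T1_SEED_GRID[k], a[k], b[k]

        def resid(x):
            return x[1] + x[2] * np.exp(-ti / x[0]) - s

        def jac(x):
            E = np.exp(-ti / x[0])
            return np.column_stack([x[2] * E * ti / x[0] ** 2, np.ones_like(ti), E])

        res = _polish(resid, [t1_0, a0, b0],
                      ([T1_BOUNDS[0], -np.inf, -np.inf],
                       [T1_BOUNDS[1], np.inf, np.inf]), jac=jac)
        t1, a, b = res.x
        return t1, {"a": a, "b": b}, np.linalg.norm(res.fun), res.success
    td = np.asarray(td, float)
    # s = m0 (1 - (1 + eps (1 - e^{-td/t1})) e^{-ti/t1}); profile m0
    f = _ir_basis(ti, td, _T1_SEED_GRID, _EPS_SEED_GRID)
    denom = (f * f).sum(axis=2)
    denom = np.where(denom <= 0, np.nan, denom)
    m0 = (f @ s) / denom
    rss = ((m0[..., None] * f - s) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.nanargmin(rss), rss.shape)
    x0 = np.array([_T1_SEED_GRID[i], _EPS_SEED_GRID[j], m0[i, j]])

    def resid(x):
        t1, eps, m0 = x
        return (
            m0 * (1.0 - (1.0 + eps * (1.0 - np.exp(-td / t1))) * np.exp(-ti / t1))
            - s
        )

    def jac(x):
        t1, eps, m0 = x
        Etd = np.exp(-td / t1)
        E = np.exp(-ti / t1)
        sat = 1.0 - Etd
        d_t1 = -m0 * (
            eps * (-Etd * td / t1**2) * E + (1.0 + eps * sat) * E * ti / t1**2
        )
        return np.column_stack([d_t1, -m0 * sat * E, 1.0 - (1.0 + eps * sat) * E])

    res = _polish(resid, np.clip(x0, [T1_BOUNDS[0], 0.0, -np.inf],
                                 [T1_BOUNDS[1], 1.2, np.inf]),
                  ([T1_BOUNDS[0], 0.0, -np.inf], [T1_BOUNDS[1], 1.2, np.inf]),
                  jac=jac)
    t1, eps, m0 = res.x
    return t1, {"eps": eps, "m0": m0}, np.linalg.norm(res.fun), res.success


_EPS_SEED_GRID = np.linspace(0.5, 1.05, 12)


def fit_ir(signal: SimulatedSignal, protocol: SequenceProtocol) -> T1Estimate:
    """Inversion-recovery fit (saturation-prepared model when the protocol
    carries TD delays, classic 3-parameter model otherwise).

    For magnitude data the polarity is restored from the seed-grid search:
    the best-fitting magnitude model assigns each sample the sign of the
    model value, and the signed fit is polished from there (the fully
    enumerated sign patterns give the same answer and are kept as a fallback
    for very small sample counts).
    """
    meta = protocol.meta
    ti = np.asarray(meta["ti_s"], float)
    td = np.asarray(meta["td_s"], float) if "td_s" in meta else None
    s = np.asarray(signal.values, float)
    if s.size != ti.size:
        raise FitError("sample count does not match the protocol's TI list")
    if s.size < 3:
        raise FitError("need at least 3 samples for an IR fit")
    if not meta.get("magnitude", False):
        t1, aux, rnorm, ok = _fit_ir_signed(ti, s, td)
        return T1Estimate(t1, aux, rnorm, ok and t1 > 0)
    mag = np.abs(s)
    if td is None:
        # the model a + b exp(-TI/T1) with b < 0 crosses zero once, so the
        # candidate polarities are prefix flips in TI order
        order = np.argsort(ti)
        patterns = [np.ones_like(mag)]
        for k in range(1, mag.size + 1):
            sign = np.ones_like(mag)
            sign[order[:k]] = -1.0
            patterns.append(sign.copy())
    else:
        # candidate polarities: the model-sign patterns of the best few cells
        # of the magnitude seed-grid search
        f = _ir_basis(ti, td, _T1_SEED_GRID, _EPS_SEED_GRID)
        denom = (f * f).sum(axis=2)
        denom = np.where(denom <= 0, np.nan, denom)
        m0 = (np.abs(f) @ mag) / denom
        rss = ((np.abs(m0[..., None] * f) - mag) ** 2).sum(axis=2)
        flat = np.argsort(rss, axis=None)[:10]
        patterns, seen = [], set()
        for idx in flat:
            i, j = np.unravel_index(idx, rss.shape)
            base = np.sign(f[i, j])
            pat = tuple(np.where(base == 0, 1.0, base))
            if pat not in seen:
                seen.add(pat)
                patterns.append(np.asarray(pat))
    best = None
    for pat in patterns:
        t1, aux, rnorm, ok = _fit_ir_signed(ti, mag * pat, td)
        if best is None or rnorm < best[2]:
            best = (t1, aux, rnorm, ok)
    t1, aux, rnorm, ok = best
    return T1Estimate(t1, aux, rnorm, ok and t1 > 0)


# ----------------------------------------------------------------------------
# saturation recovery
# ----------------------------------------------------------------------------


def fit_sr(signal: SimulatedSignal, times=None) -> T1Estimate:
    """Two-parameter saturation-recovery fit ``M0 (1 - e^{-t/T1})``."""
    s = np.asarray(signal.values, float)
    t = np.asarray(times if times is not None else signal.times, float)
    if s.size < 2:
        raise FitError("need at least 2 samples for an SR fit")
    if np.ptp(t) == 0:
        raise FitError("saturation-recovery times are degenerate")
    best = (np.inf, None)
    for t1 in _T1_SEED_GRID:
        f = 1.0 - np.exp(-t / t1)
        m0 = (f @ s) / (f @ f)
        r = m0 * f - s
        if (rss := r @ r) < best[0]:
            best = (rss, (t1, m0))

    def resid(x):
        return x[1] * (1.0 - np.exp(-t / x[0])) - s

    def jac(x):
        E = np.exp(-t / x[0])
        return np.column_stack([-x[1] * E * t / x[0] ** 2, 1.0 - E])

    res = _polish(resid, list(best[1]),
                  ([T1_BOUNDS[0], -np.inf], [T1_BOUNDS[1], np.inf]), jac=jac)
    return T1Estimate(res.x[0], {"m0": res.x[1]},
                      np.linalg.norm(res.fun), res.success)


# ----------------------------------------------------------------------------
# Look-Locker
# ----------------------------------------------------------------------------


def fit_ll(signal: SimulatedSignal, protocol: SequenceProtocol) -> T1Estimate:
    """Three-parameter fit along the readout train plus the Look-Locker
    correction ``T1 = T1* (B/A - 1)``."""
    s = np.asarray(signal.values, float)
    t = np.asarray(protocol.meta["t_s"], float)
    if s.size < 3:
        raise FitError("need at least 3 samples for a Look-Locker fit")
    t1s, aux, rnorm, ok = _fit_ir_signed(t, s)
    a, b = aux["a"], -aux["b"]  # s = a - b exp(-t/T1*)
    if a <= 0:
        raise FitError("Look-Locker fit has non-positive steady-state amplitude")
    t1 = t1s * (b / a - 1.0)
    return T1Estimate(
        t1, {"t1_star": t1s, "a": a, "b": b}, rnorm, ok and t1 > 0
    )


# ----------------------------------------------------------------------------
# variable flip angle (DESPOT1)
# ----------------------------------------------------------------------------


def fit_vfa(signals, flips, tr: float, b1_scale: float = 1.0) -> T1Estimate:
    """DESPOT1 linearization with B1 correction.

    ``signals`` are the per-flip steady-state amplitudes, ``flips`` the
    nominal flip angles in rad; the effective angles are ``b1_scale * flips``.
    """
    s = np.asarray(signals, float)
    a = b1_scale * np.asarray(flips, float)
    if s.size < 2:
        raise FitError("need at least 2 flip angles")
    y = s / np.sin(a)
    x = s / np.tan(a)
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    if not 0.0 < slope < 1.0:
        raise FitError(f"DESPOT1 slope {slope:.4f} outside (0, 1)")
    t1 = -tr / np.log(slope)
    m0 = intercept / (1.0 - slope)
    rnorm = float(np.linalg.norm(X @ np.array([slope, intercept]) - y))
    return T1Estimate(t1, {"m0": m0, "slope": slope}, rnorm, True)


# ----------------------------------------------------------------------------
# MP2RAGE
# ----------------------------------------------------------------------------

_LOOKUP_T1_GRID = np.arange(0.2, 5.0 + 1e-9, 1e-3)


_TABLE_CACHE: dict = {}


def _mp2rage_table(protocol: SequenceProtocol, t2f: float):
    """Dictionary UNI(T1) of the protocol under the mono-exponential model,
    restricted to its longest monotonic branch; cached per protocol."""
    key = (protocol.method_id, t2f)
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    sims = mono_signal_t1_grid(protocol, _LOOKUP_T1_GRID, t2f=t2f)
    s1, s2 = sims["ti1"], sims["ti2"]
    uni = s1 * s2 / (s1**2 + s2**2)
    table = _monotonic_branch(uni)
    _TABLE_CACHE[key] = table
    return table


def _monotonic_branch(uni):
    d = np.sign(np.diff(uni))
    best_lo = best_hi = lo = 0
    for i in range(1, d.size):
        if d[i] != d[i - 1] or d[i] == 0:
            if i - lo > best_hi - best_lo:
                best_lo, best_hi = lo, i
            lo = i
    if d.size - lo > best_hi - best_lo:
        best_lo, best_hi = lo, d.size
    t1b = _LOOKUP_T1_GRID[best_lo : best_hi + 1]
    unib = uni[best_lo : best_hi + 1]
    if unib[0] > unib[-1]:
        t1b, unib = t1b[::-1], unib[::-1]
    return unib, t1b


def mp2rage_t1(
    signal_pair, protocol: SequenceProtocol, t2f: float = 76.9e-3
) -> T1Estimate:
    """Invert the MP2RAGE uniform contrast through the protocol's
    mono-exponential dictionary (T1 grid 0.2–5 s, 1 ms steps)."""
    s1, s2 = float(signal_pair[0]), float(signal_pair[1])
    denom = s1**2 + s2**2
    if denom == 0:  # includes subnormal pairs whose squares underflow
        raise FitError("zero MP2RAGE signal pair")
    uni = s1 * s2 / denom
    unib, t1b = _mp2rage_table(protocol, t2f)
    inside = unib.min() <= uni <= unib.max()
    t1 = float(np.interp(uni, unib, t1b))
    return T1Estimate(
        t1,
        {"uni": uni},
        0.0,
        converged=bool(inside),
        message="" if inside else "UNI outside the monotonic dictionary range",
    )


# ----------------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------------


def _dispatch_ir(protocol, signal, b1):
    return fit_ir(signal, protocol)


def _dispatch_sr(protocol, signal, b1):
    return fit_sr(signal, np.asarray(protocol.meta["t_s"], float))


def _dispatch_ll(protocol, signal, b1):
    return fit_ll(signal, protocol)


def _dispatch_vfa(protocol, signal, b1):
    flips = np.radians(protocol.meta["flips_deg"])
    s = np.array([signal[f"fa{i}"][0] for i in range(len(flips))])
    return fit_vfa(s, flips, protocol.meta["tr_s"], b1_scale=b1)


def _dispatch_mp2rage(protocol, signal, b1):
    return mp2rage_t1(
        (signal["ti1"][0], signal["ti2"][0]), protocol
    )


FIT_PROCEDURES = {
    "ir": _dispatch_ir,
    "sr": _dispatch_sr,
    "ll": _dispatch_ll,
    "vfa": _dispatch_vfa,
    "mp2rage": _dispatch_mp2rage,
}


def dispatch_fit(
    protocol: SequenceProtocol, signal: SimulatedSignal, b1: float = 1.0
) -> T1Estimate:
    """Route simulated (or measured) samples to the protocol's published
    fitting procedure; returns a uniform :class:`T1Estimate`."""
    try:
        proc = FIT_PROCEDURES[protocol.fit_procedure]
    except KeyError:
        raise KeyError(
            f"unknown fit procedure {protocol.fit_procedure!r}"
        ) from None
    return proc(protocol, signal, b1)
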