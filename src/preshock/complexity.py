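"""Nonlinear and fractal measures for physiological series.

Entropy-family metrics (SampEn, ApEn, multiscale entropy), symbolic
complexity (Lempel-Ziv), the central tendency measure, long-range
scaling exponents (rescaled-range Hurst, DFA, multifractal DFA),
Rosenstein's largest Lyapunov exponent, Grassberger-Procaccia
correlation dimension, and Poincare descriptors.

All functions are pure and deterministic.  Degenerate inputs
(zero variance, too-short series) return documented fallback
constants or ``nan`` rather than raising, so a feature-extraction
pass over a noisy window never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricParams",
    "sample_entropy",
    "approximate_entropy",
    "multiscale_entropy",
    "lempel_ziv_complexity",
    "central_tendency_measure",
    "hurst_exponent",
    "dfa_alpha",
    "mfdfa_alpha1_peak",
    "largest_lyapunov",
    "correlation_dimension",
    "poincare_descriptors",
]

# Fallback values for zero-variance input, per metric.
_FLAT_HURST = 0.5
_FLAT_LYAPUNOV = 0.0
_FLAT_DFA = 0.5
_FLAT_MFDFA = 0.5
_FLAT_CD = 0.0


@dataclass(frozen=True)
class MetricParams:
    """Shared tunables for the complexity metrics.

    ``r_factor`` scales the series SD into the SampEn/ApEn tolerance;
    ``ctm_rho_factor`` does the same for the CTM radius.  ``mse_scales``
    are the coarse-graining factors of multiscale entropy (scale 1 is
    the raw series).  ``mfdfa_q`` is the moment range of the
    multifractal spectrum.
    """

    m: int = 2
    r_factor: float = 0.2
    ctm_rho_factor: float = 0.1
    mse_scales: tuple[int, ...] = (1, 2, 3, 4, 5)
    mfdfa_q: tuple[float, ...] = (-5, -3, -1, 0, 1, 3, 5)
    lyap_max_points: int = 400
    cd_max_points: int = 400


def _as1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def _template_max_dist(d: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    """Chebyshev distance matrix between all length-m templates.

    ``d`` is the precomputed |x_i - x_j| matrix.  Only the first
    ``n_templates`` starting indices are used so the m- and
    (m+1)-template counts can be held equal (the standard SampEn
    convention).
    """
    out = d[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(out, d[k : k + n_templates, k : k + n_templates], out)
    return out


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B) with self-matches excluded.

    ``r`` defaults to 0.2 x SD of the series (population SD), making
    the measure invariant to affine rescaling of the input.  Constant
    series return 0 by convention; series with no template matches
    return ``nan`` (missing-marker at the feature level).
    """
    x = _as1d(x)
    n = x.size
    if n < m + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    d = np.abs(x[:, None] - x[None, :])
    nt = n - m  # templates of length m and m+1, equal counts
    dm = _template_max_dist(d, m, nt)
    b = int((dm <= r).sum()) - nt
    np.maximum(dm, d[m:n, m:n], out=dm)  # extend templates to length m+1
    a = int((dm <= r).sum()) - nt
    if a <= 0 or b <= 0:
        return float("nan")
    return float(-np.log(a / b))


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = phi(m) - phi(m+1), self-matches included."""
    x = _as1d(x)
    n = x.size
    if n < m + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    d = np.abs(x[:, None] - x[None, :])

    def phi(mm: int) -> float:
        nt = n - mm + 1
        dm = _template_max_dist(d, mm, nt)
        c = (dm <= r).sum(axis=1) / nt
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def multiscale_entropy(x, m: int = 2, r: float | None = None,
                       scales: tuple[int, ...] = (1, 2, 3, 4, 5)) -> np.ndarray:
    """SampEn of coarse-grained series per scale.

    The tolerance is fixed from the scale-1 (raw) series SD, so scale 1
    reproduces :func:`sample_entropy` exactly.
    """
    x = _as1d(x)
    if r is None:
        sd = x.std()
        if sd == 0:
            return np.zeros(len(scales))
        r = 0.2 * sd
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        if s == 1:
            cg = x
        else:
            ns = x.size // s
            cg = x[: ns * s].reshape(ns, s).mean(axis=1)
        out[i] = sample_entropy(cg, m=m, r=r)
    return out


def _lz76_phrase_count(symbols: np.ndarray) -> int:
    """LZ76 production count (Kaspar-Schuster exhaustive parsing).

    Each phrase is the shortest extension not reproducible from the
    prior history with overlap allowed; the trailing phrase may be
    fully reproducible.
    """
    s = np.ascontiguousarray(symbols, dtype=np.uint8).tobytes()
    n = len(s)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and s[i : i + length] in s[: i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


def lempel_ziv_complexity(x, normalize: bool = True) -> float:
    """LZ76 complexity of the median-binarized series.

    Samples strictly above the median map to 1.  With ``normalize``,
    the phrase count c(n) is scaled by log2(n)/n so that i.i.d. noise
    approaches 1.
    """
    x = _as1d(x)
    n = x.size
    if n < 2:
        return float("nan")
    bits = (x > np.median(x)).astype(np.int8)
    c = _lz76_phrase_count(bits)
    if not normalize:
        return float(c)
    return float(c * np.log2(n) / n)


def central_tendency_measure(x, rho: float | None = None) -> float:
    """Fraction of second-difference scatter points within radius rho.

    Points are (dx_i, dx_{i+1}) from first differences; a constant
    series concentrates all points at the origin and returns 1.
    """
    x = _as1d(x)
    if x.size < 3:
        return float("nan")
    if rho is None:
        sd = x.std()
        rho = 0.1 * sd if sd > 0 else 1e-12
    d = np.diff(x)
    rad = np.hypot(d[:-1], d[1:])
    return float(np.mean(rad < rho))


def _rs_expected(n: int) -> float:
    """Anis-Lloyd-Peters expected R/S of i.i.d. noise at segment size n."""
    i = np.arange(1, n)
    front = (n - 0.5) / n
    if n <= 340:
        from scipy.special import gammaln

        g = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        g = 1.0 / np.sqrt(n * np.pi / 2.0)
    return float(front * g * np.sum(np.sqrt((n - i) / i)))


def hurst_exponent(x) -> float:
    """Hurst exponent by bias-corrected rescaled-range regression.

    The slope of log(R/S) - log(E[R/S]) against log(segment size) is
    added to 0.5 (Anis-Lloyd correction), which centres i.i.d. noise
    at H = 0.5 even for short series.
    """
    x = _as1d(x)
    n = x.size
    if n < 20:
        return float("nan")
    if x.std() == 0:
        return _FLAT_HURST
    sizes = np.unique(np.floor(np.exp(np.linspace(np.log(10), np.log(n // 2), 10))).astype(int))
    sizes = sizes[sizes >= 10]
    log_s, log_ratio = [], []
    for s in sizes:
        k = n // s
        seg = x[: k * s].reshape(k, s)
        dev = np.cumsum(seg - seg.mean(axis=1, keepdims=True), axis=1)
        rng = dev.max(axis=1) - dev.min(axis=1)
        sd = seg.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        rs = np.mean(rng[ok] / sd[ok])
        if rs <= 0:
            continue
        log_s.append(np.log(s))
        log_ratio.append(np.log(rs) - np.log(_rs_expected(int(s))))
    if len(log_s) < 3:
        return float("nan")
    slope = np.polyfit(log_s, log_ratio, 1)[0]
    return float(0.5 + slope)


def _dfa_fluctuations(x: np.ndarray, scales: np.ndarray, order: int = 1):
    """Per-scale window residual variances of the integrated profile.

    Returns (scales_used, list of per-window residual-variance arrays),
    covering the profile from both ends so trailing samples count.
    """
    prof = np.cumsum(x - x.mean())
    n = prof.size
    out_scales, out_var = [], []
    for s in scales:
        s = int(s)
        k = n // s
        if k < 2:
            continue
        t = np.arange(s, dtype=float)
        # Vandermonde pseudo-inverse shared by all windows of this scale
        v = np.vander(t, order + 1)
        pinv = np.linalg.pinv(v)
        segs = np.concatenate(
            [prof[: k * s].reshape(k, s), prof[n - k * s :].reshape(k, s)]
        )
        coef = segs @ pinv.T
        resid = segs - coef @ v.T
        out_scales.append(s)
        out_var.append(np.mean(resid**2, axis=1))
    return np.array(out_scales), out_var


def dfa_alpha(x, scale_range: tuple[int, int] | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent (order-1 DFA)."""
    x = _as1d(x)
    n = x.size
    if n < 20:
        return float("nan")
    if x.std() == 0:
        return _FLAT_DFA
    lo, hi = scale_range if scale_range else (4, max(5, n // 4))
    hi = min(hi, n // 2)
    if hi <= lo:
        return float("nan")
    scales = np.unique(np.floor(np.exp(np.linspace(np.log(lo), np.log(hi), 10))).astype(int))
    s_used, variances = _dfa_fluctuations(x, scales)
    if s_used.size < 3:
        return float("nan")
    f = np.array([np.sqrt(np.mean(v)) for v in variances])
    ok = f > 0
    if ok.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log(s_used[ok]), np.log(f[ok]), 1)[0])


def mfdfa_alpha1_peak(x, q: tuple[float, ...] = (-5, -3, -1, 0, 1, 3, 5),
                      scale_range: tuple[int, int] | None = None) -> float:
    """Mode of the multifractal singularity spectrum f(alpha).

    Generalised fluctuation functions F_q(s) give h(q); the Legendre
    transform tau(q) = q h(q) - 1 yields alpha = dtau/dq and
    f(alpha) = q alpha - tau.  The returned value is alpha at the
    spectrum maximum (the alpha_1 peak).
    """
    x = _as1d(x)
    n = x.size
    if n < 30:
        return float("nan")
    if x.std() == 0:
        return _FLAT_MFDFA
    lo, hi = scale_range if scale_range else (8, max(9, n // 4))
    hi = min(hi, n // 2)
    if hi <= lo:
        return float("nan")
    scales = np.unique(np.floor(np.exp(np.linspace(np.log(lo), np.log(hi), 8))).astype(int))
    s_used, variances = _dfa_fluctuations(x, scales)
    if s_used.size < 3:
        return float("nan")
    qs = np.asarray(q, dtype=float)
    log_f = np.empty((qs.size, s_used.size))
    for j, v in enumerate(variances):
        v = np.maximum(v, 1e-30)
        for i, qq in enumerate(qs):
            if qq == 0:
                log_f[i, j] = 0.5 * np.mean(np.log(v))
            else:
                log_f[i, j] = np.log(np.mean(v ** (qq / 2.0))) / qq
    ls = np.log(s_used)
    h = np.array([np.polyfit(ls, log_f[i], 1)[0] for i in range(qs.size)])
    tau = qs * h - 1.0
    qm = 0.5 * (qs[1:] + qs[:-1])
    alpha = np.diff(tau) / np.diff(qs)
    tau_m = 0.5 * (tau[1:] + tau[:-1])
    f_alpha = qm * alpha - tau_m
    return float(alpha[int(np.argmax(f_alpha))])


def largest_lyapunov(x, m: int = 2, delay: int = 1, min_sep: int | None = None,
                     follow: int = 8, max_points: int = 400) -> float:
    """Largest Lyapunov exponent by Rosenstein's divergence-slope method.

    The series is delay-embedded, each point paired with its nearest
    neighbour at temporal separation > ``min_sep``, and the mean log
    divergence over ``follow`` steps is regressed on step count.
    Long inputs are evenly subsampled to ``max_points`` embeddings for
    tractability; the estimator is reported per (possibly strided)
    step.
    """
    x = _as1d(x)
    if x.std() == 0:
        return _FLAT_LYAPUNOV
    stride = max(1, int(np.ceil(x.size / max_points)))
    x = x[::stride]
    n = x.size - (m - 1) * delay
    if n < follow + 10:
        return float("nan")
    emb = np.column_stack([x[i * delay : i * delay + n] for i in range(m)])
    if min_sep is None:
        min_sep = max(1, n // 50)
    d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= min_sep
    d_masked = np.where(band, np.inf, d)
    usable = n - follow
    nn = np.argmin(d_masked[:usable, :usable], axis=1)
    div = np.empty(follow + 1)
    for k in range(follow + 1):
        dk = np.linalg.norm(emb[idx[:usable] + k] - emb[nn + k], axis=1)
        good = dk > 0
        div[k] = np.mean(np.log(dk[good])) if good.any() else np.nan
    ks = np.arange(follow + 1)
    good = np.isfinite(div)
    if good.sum() < 3:
        return float("nan")
    return float(np.polyfit(ks[good], div[good], 1)[0])


def correlation_dimension(x, m: int = 2, delay: int = 1,
                          max_points: int = 400) -> float:
    """Grassberger-Procaccia correlation dimension estimate.

    Slope of log C(r) versus log r over the 10th-60th percentile of
    the pairwise embedded distances.
    """
    x = _as1d(x)
    if x.std() == 0:
        return _FLAT_CD
    stride = max(1, int(np.ceil(x.size / max_points)))
    x = x[::stride]
    n = x.size - (m - 1) * delay
    if n < 20:
        return float("nan")
    emb = np.column_stack([x[i * delay : i * delay + n] for i in range(m)])
    d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    dists = dists[dists > 0]
    if dists.size < 10:
        return float("nan")
    r_lo, r_hi = np.percentile(dists, [10, 60])
    if r_lo <= 0 or r_hi <= r_lo:
        return float("nan")
    rs = np.exp(np.linspace(np.log(r_lo), np.log(r_hi), 8))
    c = np.array([np.mean(dists < r) for r in rs])
    ok = c > 0
    if ok.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log(rs[ok]), np.log(c[ok]), 1)[0])


def poincare_descriptors(rr) -> tuple[float, float]:
    """Poincare SD1/SD2 of an interval series (population statistics).

    SD1 = SD(successive differences)/sqrt(2); SD2 follows from the
    identity SD1^2 + SD2^2 = 2 SD(rr)^2.
    """
    rr = _as1d(rr)
    if rr.size < 3:
        return float("nan"), float("nan")
    sd1 = float(np.std(np.diff(rr)) / np.sqrt(2.0))
    sd2_sq = 2.0 * float(np.std(rr)) ** 2 - sd1**2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    return sd1, sd2
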