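"""Heart-rate-variability indices computed from an NN-interval series.

The panel mirrors the variable set used to train the screening model:
time-domain statistics, high-frequency spectral power, heart-rate
fragmentation (Costa et al. 2017), Poincaré-plot geometry including the
asymmetry decomposition of Piskorski & Guzik (2011), detrended fluctuation
analysis and its multifractal extension, and a set of complexity/entropy
indices. All indices operate on NN intervals in **milliseconds**.

Estimators that are undefined for a given series (too few beats for DFA,
zero dispersion for ratio indices, ...) return ``NaN`` rather than raising:
downstream filtering treats these as missing values, which is exactly how
short 20 s snippets behave with the fragile multifractal estimators.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate, signal

__all__ = ["FEATURE_NAMES", "hrv_features"]

#: histogram bin width used by the geometric indices (ms); 1/128 s is the
#: conventional Task-Force discretisation
_BIN_WIDTH_MS = 1000.0 / 128.0

#: canonical column order of the feature panel
FEATURE_NAMES = (
    # time domain
    "HRV_MedianNN",
    "HRV_MadNN",
    "HRV_Prc20NN",
    "HRV_Prc80NN",
    "HRV_pNN50",
    "HRV_pNN20",
    "HRV_MinNN",
    "HRV_HTI",
    "HRV_TINN",
    # frequency domain
    "HRV_HF",
    "HRV_HFn",
    # heart-rate fragmentation
    "HRV_PIP",
    "HRV_PSS",
    "HRV_PAS",
    # Poincaré geometry
    "HRV_SD1SD2",
    "HRV_CSI",
    "HRV_CVI",
    "HRV_CSI_Modified",
    "HRV_GI",
    "HRV_PI",
    "HRV_C1d",
    "HRV_SD1d",
    "HRV_C2d",
    "HRV_SD2d",
    "HRV_SD2a",
    "HRV_Cd",
    # DFA / multifractal DFA
    "HRV_DFA_alpha1",
    "HRV_MFDFA_alpha1_Width",
    "HRV_MFDFA_alpha1_Peak",
    "HRV_MFDFA_alpha1_Mean",
    "HRV_MFDFA_alpha1_Max",
    "HRV_MFDFA_alpha1_Delta",
    "HRV_MFDFA_alpha1_Asymmetry",
    "HRV_MFDFA_alpha1_Fluctuation",
    # complexity
    "HRV_ApEn",
    "HRV_ShanEn",
    "HRV_FuzzyEn",
    "HRV_CD",
    "HRV_HFD",
    "HRV_KFD",
    "HRV_LZC",
)


def hrv_features(rr_ms: np.ndarray) -> dict[str, float]:
    """Compute the full HRV panel from NN intervals in milliseconds.

    Requires at least 3 intervals (closed-form indices are defined from
    there; underpowered estimators return ``NaN``). Returns a dict keyed by
    :data:`FEATURE_NAMES`; indices whose estimator fails on the given series
    are ``NaN``.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.ndim != 1:
        raise ValueError("rr_ms must be one-dimensional")
    if rr.size < 3:
        raise ValueError(f"need at least 3 NN intervals, got {rr.size}")
    if not np.all(np.isfinite(rr)) or np.any(rr <= 0):
        raise ValueError("NN intervals must be finite and positive")

    out: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}
    diff = np.diff(rr)

    # --- time domain ------------------------------------------------------
    med = float(np.median(rr))
    out["HRV_MedianNN"] = med
    out["HRV_MadNN"] = 1.4826 * float(np.median(np.abs(rr - med)))
    out["HRV_Prc20NN"] = float(np.percentile(rr, 20))  # linear interpolation
    out["HRV_Prc80NN"] = float(np.percentile(rr, 80))
    out["HRV_pNN50"] = 100.0 * float(np.mean(np.abs(diff) > 50.0))
    out["HRV_pNN20"] = 100.0 * float(np.mean(np.abs(diff) > 20.0))
    out["HRV_MinNN"] = float(np.min(rr))
    counts, edges = _rr_histogram(rr)
    out["HRV_HTI"] = rr.size / float(counts.max())
    out["HRV_TINN"] = _tinn(counts, edges)

    # --- frequency domain -------------------------------------------------
    hf, hfn = _hf_power(rr)
    out["HRV_HF"] = hf
    out["HRV_HFn"] = hfn

    # --- fragmentation ----------------------------------------------------
    out.update(_fragmentation(diff))

    # --- Poincaré geometry ------------------------------------------------
    out.update(_poincare(rr))

    # --- DFA --------------------------------------------------------------
    out["HRV_DFA_alpha1"] = _dfa_alpha1(rr)
    out.update(_mfdfa_alpha1(rr))

    # --- complexity -------------------------------------------------------
    sd = float(np.std(rr, ddof=1))
    out["HRV_ApEn"] = _apen(rr, m=2, r=0.2 * sd) if sd > 0 else np.nan
    out["HRV_ShanEn"] = _shannon_entropy(counts)
    out["HRV_FuzzyEn"] = _fuzzyen(rr, m=2, r=0.2 * sd) if sd > 0 else np.nan
    out["HRV_CD"] = _correlation_dimension(rr)
    out["HRV_HFD"] = _higuchi_fd(rr)
    out["HRV_KFD"] = _katz_fd(rr)
    out["HRV_LZC"] = _lempel_ziv(rr)
    return out


# ---------------------------------------------------------------------------
# geometric helpers


def _rr_histogram(rr):
    lo = np.floor(rr.min() / _BIN_WIDTH_MS) * _BIN_WIDTH_MS
    hi = np.ceil(rr.max() / _BIN_WIDTH_MS) * _BIN_WIDTH_MS
    if hi <= lo:
        hi = lo + _BIN_WIDTH_MS
    edges = np.arange(lo, hi + _BIN_WIDTH_MS / 2, _BIN_WIDTH_MS)
    counts, _ = np.histogram(rr, bins=edges)
    return counts, edges


def _tinn(counts, edges):
    """Baseline width of the best triangular fit to the RR histogram (ms).

    Grid search over (N, M) around the histogram peak minimising the squared
    error of the triangle through (N, 0), (peak, peak height), (M, 0).
    """
    if (counts > 0).sum() < 2:
        return 0.0
    centers = (edges[:-1] + edges[1:]) / 2.0
    ipk = int(np.argmax(counts))
    peak_x, peak_y = centers[ipk], counts[ipk]
    # candidate baseline endpoints, one bin beyond the range on both sides
    left = np.concatenate([[centers[0] - _BIN_WIDTH_MS], centers[: ipk + 1]])
    right = np.concatenate([centers[ipk:], [centers[-1] + _BIN_WIDTH_MS]])
    best = (np.inf, 0.0)
    for nx in left:
        if nx >= peak_x:
            continue
        for mx in right:
            if mx <= peak_x:
                continue
            tri = np.zeros_like(centers, dtype=float)
            up = (centers > nx) & (centers <= peak_x)
            dn = (centers > peak_x) & (centers < mx)
            tri[up] = peak_y * (centers[up] - nx) / (peak_x - nx)
            tri[dn] = peak_y * (mx - centers[dn]) / (mx - peak_x)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, mx - nx)
    return float(best[1])


# ---------------------------------------------------------------------------
# frequency domain


def _hf_power(rr):
    """HF (0.15-0.4 Hz) power and HF normalised by LF+HF.

    The tachogram is resampled at 4 Hz by cubic interpolation over the beat
    times before Welch estimation. Short snippets give crude estimates; that
    is inherent to 20 s windows, not an implementation artefact.
    """
    t = np.cumsum(rr) / 1000.0
    t = t - t[0]
    if t[-1] < 10.0 or rr.size < 6:
        return np.nan, np.nan
    fs = 4.0
    ti = np.arange(0.0, t[-1], 1.0 / fs)
    kind = "cubic" if rr.size >= 4 else "linear"
    x = interpolate.interp1d(t, rr, kind=kind, fill_value="extrapolate")(ti)
    x = x - np.mean(x)
    if np.allclose(x, 0.0):
        return 0.0, np.nan
    nperseg = min(256, x.size)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg, detrend="linear")
    lf = float(np.trapezoid(psd[(freqs >= 0.04) & (freqs < 0.15)],
                            freqs[(freqs >= 0.04) & (freqs < 0.15)]))
    hf = float(np.trapezoid(psd[(freqs >= 0.15) & (freqs < 0.40)],
                            freqs[(freqs >= 0.15) & (freqs < 0.40)]))
    total = lf + hf
    return hf, (hf / total if total > 0 else np.nan)


# ---------------------------------------------------------------------------
# heart-rate fragmentation (Costa et al. 2017)


def _fragmentation(diff):
    n = diff.size
    if n < 3:
        return {"HRV_PIP": np.nan, "HRV_PSS": np.nan, "HRV_PAS": np.nan}
    s = np.sign(diff)
    # inflection points: sign changes of the increment series (zeros count
    # as changes, as in the original definition)
    change = (s[1:] != s[:-1]) | (s[1:] == 0)
    pip = 100.0 * float(np.sum(change)) / n

    # accel/decel segments: maximal runs of constant sign
    seg_lengths = []
    run = 1
    for i in range(1, n):
        if s[i] == s[i - 1] and s[i] != 0:
            run += 1
        else:
            seg_lengths.append(run)
            run = 1
    seg_lengths.append(run)
    short = sum(length for length in seg_lengths if length < 3)
    pss = 100.0 * short / n

    # alternation segments: maximal runs of strictly alternating sign,
    # counted when at least 4 increments long
    alt_total = 0
    run = 1
    for i in range(1, n):
        if s[i] == -s[i - 1] and s[i] != 0:
            run += 1
        else:
            if run >= 4:
                alt_total += run
            run = 1
    if run >= 4:
        alt_total += run
    pas = 100.0 * alt_total / n
    return {"HRV_PIP": pip, "HRV_PSS": pss, "HRV_PAS": pas}


# ---------------------------------------------------------------------------
# Poincaré geometry


def _poincare(rr):
    x, y = rr[:-1], rr[1:]
    n_pairs = x.size
    diff = y - x
    sd1 = float(np.sqrt(np.var(diff, ddof=1) / 2.0))
    sdnn2 = float(np.var(rr, ddof=1))
    sd2 = float(np.sqrt(max(2.0 * sdnn2 - sd1**2, 0.0)))

    out = {}
    out["HRV_SD1SD2"] = sd1 / sd2 if sd2 > 0 else np.nan
    out["HRV_CSI"] = sd2 / sd1 if sd1 > 0 else np.nan
    out["HRV_CVI"] = np.log10(16.0 * sd1 * sd2) if sd1 > 0 and sd2 > 0 else np.nan
    out["HRV_CSI_Modified"] = (16.0 * sd2**2) / (4.0 * sd1) if sd1 > 0 else np.nan

    # Guzik's and Porta's indices of heart-rate asymmetry
    dist = np.abs(diff) / np.sqrt(2.0)
    above = diff > 0  # decelerations lie above the line of identity
    below = diff < 0
    total_dist = float(dist.sum())
    out["HRV_GI"] = 100.0 * float(dist[above].sum()) / total_dist if total_dist > 0 else np.nan
    off_line = int(above.sum() + below.sum())
    out["HRV_PI"] = 100.0 * float(below.sum()) / off_line if off_line > 0 else np.nan

    # Piskorski & Guzik (2011) deceleration/acceleration decomposition
    st = diff / np.sqrt(2.0)
    lt = (x + y - 2.0 * float(np.mean(rr))) / np.sqrt(2.0)
    nochange = diff == 0
    denom = n_pairs - 1 if n_pairs > 1 else 1
    sd1d = np.sqrt(np.sum(st[above] ** 2) / denom)
    sd1a = np.sqrt(np.sum(st[below] ** 2) / denom)
    sd2d = np.sqrt((np.sum(lt[above] ** 2) + 0.5 * np.sum(lt[nochange] ** 2)) / denom)
    sd2a = np.sqrt((np.sum(lt[below] ** 2) + 0.5 * np.sum(lt[nochange] ** 2)) / denom)
    sd1i2 = sd1d**2 + sd1a**2
    sd2i2 = sd2d**2 + sd2a**2
    out["HRV_SD1d"] = float(sd1d)
    out["HRV_SD2d"] = float(sd2d)
    out["HRV_SD2a"] = float(sd2a)
    out["HRV_C1d"] = float(sd1d**2 / sd1i2) if sd1i2 > 0 else np.nan
    out["HRV_C2d"] = float(sd2d**2 / sd2i2) if sd2i2 > 0 else np.nan
    sdnnd2 = 0.5 * (sd1d**2 + sd2d**2)
    sdnna2 = 0.5 * (sd1a**2 + sd2a**2)
    out["HRV_Cd"] = float(sdnnd2 / (sdnnd2 + sdnna2)) if (sdnnd2 + sdnna2) > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# detrended fluctuation analysis


def _dfa_fluctuations(rr, scales, q=None):
    """Root-mean-square (or q-th order) fluctuation per scale.

    Returns None when the series is too short for the requested scales.
    """
    n = rr.size
    y = np.cumsum(rr - np.mean(rr))
    fluct = []
    for s in scales:
        n_win = n // s
        if n_win < 2:
            return None
        segs = y[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        # linear detrend per window via least squares
        tc = t - t.mean()
        denom = float(np.sum(tc**2))
        slopes = segs @ tc / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tc[None, :]
        f2 = np.mean(resid**2, axis=1)  # per-window mean squared fluctuation
        if q is None:
            fluct.append(np.sqrt(np.mean(f2)))
        else:
            fluct.append(f2)
    return fluct


def _dfa_alpha1(rr, scales=range(4, 17)):
    """Short-range DFA scaling exponent over window sizes 4-16 beats."""
    if rr.size < 16:
        return np.nan
    scales = list(scales)
    fl = _dfa_fluctuations(rr, scales)
    if fl is None or np.any(np.asarray(fl) <= 0):
        return np.nan
    slope = np.polyfit(np.log(scales), np.log(fl), 1)[0]
    return float(slope)


def _mfdfa_alpha1(rr, scales=range(4, 17), qs=np.arange(-5, 6)):
    """Multifractal DFA singularity-spectrum summaries over scales 4-16.

    h(q) exponents are estimated per moment order q (the q=0 case via the
    logarithmic average), the mass exponent tau(q) = q h(q) - 1 is
    differentiated numerically to get the singularity strengths alpha and
    spectrum D(alpha). Summary definitions:

    * Width  — alpha_max - alpha_min
    * Peak   — alpha at the maximum of D(alpha)
    * Mean   — mean of the singularity strengths
    * Max    — midpoint (alpha_max + alpha_min) / 2
    * Delta  — D at alpha_max minus D at alpha_min
    * Asymmetry — (alpha_peak - alpha_min) / Width (0.5 = symmetric)
    * Fluctuation — range of the generalized Hurst exponents h(q)
    """
    nan = {
        f"HRV_MFDFA_alpha1_{k}": np.nan
        for k in ("Width", "Peak", "Mean", "Max", "Delta", "Asymmetry", "Fluctuation")
    }
    if rr.size < 20:
        return nan
    scales = np.asarray(list(scales))
    per_scale = _dfa_fluctuations(rr, scales, q=True)
    if per_scale is None:
        return nan
    logs = np.log(scales.astype(float))
    hq = []
    for q in qs:
        fq = []
        for f2 in per_scale:
            f2 = np.maximum(f2, 1e-300)
            if q == 0:
                fq.append(np.exp(0.5 * np.mean(np.log(f2))))
            else:
                fq.append(np.mean(f2 ** (q / 2.0)) ** (1.0 / q))
        fq = np.asarray(fq)
        if np.any(fq <= 0) or not np.all(np.isfinite(fq)):
            return nan
        hq.append(np.polyfit(logs, np.log(fq), 1)[0])
    hq = np.asarray(hq)
    tau = qs * hq - 1.0
    alpha = np.gradient(tau, qs.astype(float))
    dspec = qs * alpha - tau
    if not np.all(np.isfinite(alpha)):
        return nan
    a_min, a_max = float(alpha.min()), float(alpha.max())
    width = a_max - a_min
    peak = float(alpha[np.argmax(dspec)])
    return {
        "HRV_MFDFA_alpha1_Width": width,
        "HRV_MFDFA_alpha1_Peak": peak,
        "HRV_MFDFA_alpha1_Mean": float(np.mean(alpha)),
        "HRV_MFDFA_alpha1_Max": (a_max + a_min) / 2.0,
        "HRV_MFDFA_alpha1_Delta": float(dspec[np.argmax(alpha)] - dspec[np.argmin(alpha)]),
        "HRV_MFDFA_alpha1_Asymmetry": (peak - a_min) / width if width > 0 else np.nan,
        "HRV_MFDFA_alpha1_Fluctuation": float(hq.max() - hq.min()),
    }


# ---------------------------------------------------------------------------
# complexity / entropy


def _embed(x, m):
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _apen(x, m=2, r=None):
    """Approximate entropy with Chebyshev distance and self-matches included."""
    n = x.size
    if n < m + 2 or r is None or r <= 0:
        return np.nan

    def phi(mm):
        emb = _embed(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = np.mean(d <= r, axis=1)
        return np.mean(np.log(c))

    return float(phi(m) - phi(m + 1))


def _fuzzyen(x, m=2, r=None, p=2):
    """Fuzzy entropy: Gaussian membership exp(-(d/r)^p) on centred templates."""
    n = x.size
    if n < m + 2 or r is None or r <= 0:
        return np.nan

    def phi(mm):
        emb = _embed(x, mm)
        emb = emb - emb.mean(axis=1, keepdims=True)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        iu = np.triu_indices(d.shape[0], k=1)
        mu = np.exp(-((d[iu] / r) ** p))
        return np.mean(mu)

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return np.nan
    return float(np.log(p_m) - np.log(p_m1))


def _shannon_entropy(counts):
    """Shannon entropy (bits) of the binned RR distribution."""
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-np.sum(p * np.log2(p)))


def _correlation_dimension(x, m=2):
    """Grassberger–Procaccia lower-bound estimate of the fractal dimension."""
    if x.size < m + 5:
        return np.nan
    emb = _embed(x, m)
    from scipy.spatial.distance import pdist

    d = pdist(emb, metric="chebyshev")
    d = d[d > 0]
    if d.size < 10:
        return np.nan
    radii = np.percentile(d, [15, 25, 35, 50, 65])
    radii = np.unique(radii[radii > 0])
    if radii.size < 3:
        return np.nan
    c = np.array([np.mean(d <= r) for r in radii])
    if np.any(c <= 0):
        return np.nan
    return float(np.polyfit(np.log(radii), np.log(c), 1)[0])


def _higuchi_fd(x, kmax=None):
    n = x.size
    kmax = kmax or min(10, n // 2)
    if kmax < 2:
        return np.nan
    lk = []
    ks = range(1, kmax + 1)
    for k in ks:
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            lm = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (((idx.size - 1) * k) * k)
            lengths.append(lm)
        if not lengths:
            return np.nan
        lk.append(np.mean(lengths))
    lk = np.asarray(lk)
    if np.any(lk <= 0):
        return np.nan
    return float(-np.polyfit(np.log(list(ks)), np.log(lk), 1)[0])


def _katz_fd(x):
    n = x.size - 1
    length = float(np.sum(np.abs(np.diff(x))))
    if length == 0:
        return np.nan
    d = float(np.max(np.abs(x - x[0])))
    if d == 0:
        return np.nan
    denom = np.log10(n) + np.log10(d / length)
    if denom == 0:
        return np.nan
    return float(np.log10(n) / denom)


def _lempel_ziv(x):
    """Normalised Lempel–Ziv complexity of the median-binarised series."""
    med = np.median(x)
    s = "".join("1" if v >= med else "0" for v in x)
    n = len(s)
    if n < 2:
        return np.nan
    substrings = {s[0]}
    # LZ76 parsing into novel phrases
    phrases = []
    start = 0
    while start < n:
        end = start + 1
        while end <= n and s[start:end] in substrings:
            end += 1
        phrase = s[start:end]
        substrings.update(s[j:k2] for j in range(start, end) for k2 in range(j + 1, end + 1))
        phrases.append(phrase)
        start = end
    c = len(phrases)
    return float(c * np.log2(n) / n)
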