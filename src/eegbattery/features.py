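"""Per-channel EEG metric families.

Six families are computed from an :class:`~eegbattery.cohort.EpochedEEG`:
narrowband power spectra (Gaussian frequency-domain convolution), aperiodic
1/f fit (exponent/offset), peak alpha frequency, phase-amplitude coupling
(Tort modulation index), multiscale sample entropy, and inter-site phase
clustering on surface-Laplacian-transformed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import eval_legendre

from eegbattery.cohort import EpochedEEG
from eegbattery.registry import BANDS, ParticipantMetrics, VariableRegistry

__all__ = [
    "SpectrumSet",
    "AperiodicFit",
    "PAFResult",
    "default_grid",
    "gaussian_narrowband_power",
    "fit_aperiodic",
    "peak_alpha",
    "tort_mi",
    "pac_band_pair",
    "sample_entropy",
    "multiscale_entropy",
    "surface_laplacian",
    "ispc",
    "extract_participant_metrics",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def default_grid(n: int = 100, lo: float = 2.0, hi: float = 80.0) -> np.ndarray:
    """Logarithmically spaced analysis frequency grid (100 points, 2-80 Hz)."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def default_fwhm(grid: np.ndarray) -> np.ndarray:
    """Proportional-bandwidth filter widths: max(0.25 f, 1 Hz)."""
    return np.maximum(0.25 * np.asarray(grid, dtype=float), 1.0)


@dataclass
class SpectrumSet:
    """Per-channel narrowband power in absolute, relative, and log10 forms."""

    grid: np.ndarray
    absolute: np.ndarray  # (n_channels, n_freqs), µV²
    relative: np.ndarray
    log: np.ndarray
    channel_names: list[str]


@dataclass
class AperiodicFit:
    exponent: float
    offset: float  # log10(µV²) at 1 Hz
    r_squared: float
    fit_range: tuple[float, float]


@dataclass
class PAFResult:
    frequency: float  # Hz, NaN if no peak in the candidate range
    amplitude: float  # power above the aperiodic fit, NaN if absent

    @property
    def present(self) -> bool:
        return np.isfinite(self.frequency)


def _analytic_narrowband(data: np.ndarray, fs: float, centre: float, fwhm: float) -> np.ndarray:
    """Complex analytic signal band-limited by a Gaussian centred at `centre`.

    The epoch spectrum is multiplied by a Gaussian over positive frequencies
    (negative frequencies zeroed, one-sided doubling), i.e. a band-pass and
    Hilbert transform in one step.  `data` is (..., n_samples).
    """
    n = data.shape[-1]
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    sigma = fwhm / _FWHM_TO_SIGMA
    gauss = np.exp(-0.5 * ((freqs - centre) / sigma) ** 2)
    gauss[freqs < 0] = 0.0
    weight = 2.0 * gauss
    weight[0] = gauss[0]
    spec = np.fft.fft(data, axis=-1)
    return np.fft.ifft(spec * weight, axis=-1)


def gaussian_narrowband_power(
    eeg: EpochedEEG,
    grid: np.ndarray | None = None,
    fwhm: np.ndarray | None = None,
) -> SpectrumSet:
    """Narrowband power at each grid frequency via Gaussian spectral filtering.

    For each frequency the epoch spectra are multiplied by a Gaussian
    centred there, the analytic signal reconstructed, and squared magnitude
    averaged over time and epochs.  Relative power is each channel's
    fraction of its total over the grid (NaN when total power is zero);
    log form is log10 of absolute power (NaN at zero power).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if fwhm is None:
        fwhm = default_fwhm(grid)
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), grid.shape)
    nyquist = eeg.sampling_rate / 2.0
    if np.any(grid >= nyquist) or np.any(grid <= 0):
        raise ValueError("grid frequencies must lie in (0, Nyquist)")
    if np.any(fwhm <= 0):
        raise ValueError("fwhm must be positive")

    n_ch = eeg.n_channels
    absolute = np.empty((n_ch, grid.size))
    spec = np.fft.fft(eeg.data, axis=-1)
    freqs = np.fft.fftfreq(eeg.n_samples, d=1.0 / eeg.sampling_rate)
    for i, (fc, w) in enumerate(zip(grid, fwhm)):
        sigma = w / _FWHM_TO_SIGMA
        gauss = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
        gauss[freqs < 0] = 0.0
        weight = 2.0 * gauss
        weight[0] = gauss[0]
        analytic = np.fft.ifft(spec * weight, axis=-1)
        absolute[:, i] = np.mean(np.abs(analytic) ** 2, axis=(0, 2))

    totals = absolute.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(totals > 0, absolute / totals, np.nan)
        log = np.where(absolute > 0, np.log10(np.where(absolute > 0, absolute, 1.0)), np.nan)
    return SpectrumSet(
        grid=grid, absolute=absolute, relative=relative, log=log,
        channel_names=list(eeg.layout.names),
    )


def _log_gauss(f: np.ndarray, height: float, mean: float, sd: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((f - mean) / sd) ** 2)


def fit_aperiodic(
    grid: np.ndarray,
    power: np.ndarray,
    fit_range: tuple[float, float] = (2.0, 40.0),
    max_peaks: int = 6,
) -> AperiodicFit:
    """Knee-free aperiodic fit: log10 P = offset - exponent * log10 f.

    Oscillatory peaks are removed iteratively: fit a line in log-log space,
    locate the largest positive residual, fit and subtract a Gaussian bump,
    repeat; the final line is fit to the peak-subtracted spectrum.
    """
    grid = np.asarray(grid, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (grid >= fit_range[0]) & (grid <= fit_range[1])
    if mask.sum() < 10:
        raise ValueError("need at least 10 grid points inside the fit range")
    f = grid[mask]
    p = power[mask]
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise ValueError("power must be positive and finite inside the fit range")

    x = np.log10(f)
    y_flat = np.log10(p)
    for _ in range(max_peaks):
        slope, intercept = np.polyfit(x, y_flat, 1)
        resid = y_flat - (slope * x + intercept)
        i = int(np.argmax(resid))
        if resid[i] < max(2.0 * resid.std(), 0.02):
            break
        try:
            popt, _ = curve_fit(
                _log_gauss,
                f,
                np.clip(resid, 0.0, None),
                p0=[resid[i], f[i], 1.0],
                bounds=([0.0, f[0], 0.1], [np.inf, f[-1], (f[-1] - f[0])]),
                maxfev=2000,
            )
        except RuntimeError:
            break
        y_flat = y_flat - _log_gauss(f, *popt)

    slope, intercept = np.polyfit(x, y_flat, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y_flat - pred) ** 2))
    ss_tot = float(np.sum((y_flat - y_flat.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-12 else 1.0 - ss_res / max(ss_tot, 1e-300)
    return AperiodicFit(
        exponent=float(-slope),
        offset=float(intercept),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        fit_range=fit_range,
    )


def peak_alpha(
    grid: np.ndarray,
    power: np.ndarray,
    candidate: tuple[float, float] = (6.0, 14.0),
    height_fraction: float = 0.05,
    aperiodic: AperiodicFit | None = None,
) -> PAFResult:
    """Best-fitting single Gaussian above the aperiodic fit in 6-14 Hz.

    The Gaussian mean/height are found by grid search over candidate means
    and widths (least squares on the aperiodic-subtracted linear power),
    then polished with a local fit.  Returns NaN frequency when no point
    exceeds the aperiodic fit by ``height_fraction`` of its local value.
    """
    grid = np.asarray(grid, dtype=float)
    power = np.asarray(power, dtype=float)
    if grid.min() > candidate[0] or grid.max() < candidate[1]:
        raise ValueError("spectrum must cover the candidate range")
    if aperiodic is None:
        aperiodic = fit_aperiodic(grid, power)
    ap = 10.0 ** (aperiodic.offset - aperiodic.exponent * np.log10(grid))
    mask = (grid >= candidate[0]) & (grid <= candidate[1])
    f = grid[mask]
    resid = power[mask] - ap[mask]
    floor = height_fraction * ap[mask]
    if not np.any(resid > floor):
        return PAFResult(frequency=np.nan, amplitude=np.nan)

    best = (np.inf, f[int(np.argmax(resid))], float(resid.max()), 1.0)
    for mean in f:
        for sd in (0.5, 1.0, 2.0, 3.0):
            basis = np.exp(-0.5 * ((f - mean) / sd) ** 2)
            denom = float(basis @ basis)
            height = max(float(basis @ resid) / denom, 0.0) if denom > 0 else 0.0
            sse = float(np.sum((resid - height * basis) ** 2))
            if sse < best[0]:
                best = (sse, mean, height, sd)
    _, mean0, height0, sd0 = best
    try:
        popt, _ = curve_fit(
            _log_gauss, f, resid, p0=[height0, mean0, sd0],
            bounds=([0.0, candidate[0], 0.1], [np.inf, candidate[1], 8.0]),
            maxfev=2000,
        )
        height0, mean0, sd0 = float(popt[0]), float(popt[1]), float(popt[2])
    except RuntimeError:
        pass
    # a mean pinned to the candidate edge indicates an out-of-range peak's tail
    edge = 0.25
    if mean0 <= candidate[0] + edge or mean0 >= candidate[1] - edge:
        return PAFResult(frequency=np.nan, amplitude=np.nan)
    return PAFResult(frequency=float(mean0), amplitude=float(height0))


def tort_mi(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18) -> float:
    """Modulation index: normalized KL divergence of the phase-amplitude profile.

    Mean amplitude is computed within phase bins, normalized to a
    distribution p; MI = (log N - H(p)) / log N.  Returns NaN when the
    total binned amplitude is zero (no amplitude information).
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        return np.nan
    p = means / total
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    return float((np.log(n_bins) - entropy) / np.log(n_bins))


def _band_centre_fwhm(band: str) -> tuple[float, float]:
    lo, hi = BANDS[band]
    return 0.5 * (lo + hi), hi - lo


def pac_band_pair(
    eeg: EpochedEEG, phase_band: str, amplitude_band: str, n_bins: int = 18
) -> np.ndarray:
    """Per-channel Tort MI between a low band's phase and a high band's amplitude.

    Epochs are filtered independently, then phase/amplitude series are
    concatenated across epochs before binning.
    """
    pc, pw = _band_centre_fwhm(phase_band)
    ac, aw = _band_centre_fwhm(amplitude_band)
    if pc > ac:
        raise ValueError("phase band centre must not exceed amplitude band centre")
    phase = np.angle(_analytic_narrowband(eeg.data, eeg.sampling_rate, pc, pw))
    amp = np.abs(_analytic_narrowband(eeg.data, eeg.sampling_rate, ac, aw))
    n_ch = eeg.n_channels
    out = np.empty(n_ch)
    for c in range(n_ch):
        out[c] = tort_mi(phase[:, c, :].ravel(), amp[:, c, :].ravel(), n_bins)
    return out


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r) with Chebyshev distance and tolerance `r` in data units.

    Counts template pairs (i < j, both drawn from the first N-m templates)
    matching within r at length m (B) and at length m+1 (A); returns
    -ln(A/B), NaN when either count is zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < m + 2:
        return np.nan
    n_templates = n - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    d_m = np.max(np.abs(emb_m[:, None, :] - emb_m[None, :, :]), axis=-1)
    d_m1 = np.max(np.abs(emb_m1[:, None, :] - emb_m1[None, :, :]), axis=-1)
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if a == 0 or b == 0:
        return np.nan if a != b else 0.0
    return float(-np.log(a / b))


def multiscale_entropy(
    eeg: EpochedEEG, n_scales: int = 20, m: int = 2, r: float = 0.2
) -> np.ndarray:
    """Per-channel sample entropy over coarse-graining scales 1..n_scales.

    At scale tau the epoch signal is averaged in non-overlapping blocks of
    tau samples; tolerance is r times the SD of that epoch's original
    (scale-1) series, held fixed across scales.  Entropies are averaged
    over epochs; scales whose coarse-grained length is < 10 (m+1) are NaN.
    """
    n_ch = eeg.n_channels
    out = np.full((n_ch, n_scales), np.nan)
    min_len = 10 * (m + 1)
    for c in range(n_ch):
        per_scale = np.full((eeg.n_epochs, n_scales), np.nan)
        for e in range(eeg.n_epochs):
            sig = eeg.data[e, c]
            tol = r * sig.std(ddof=0)
            for s in range(1, n_scales + 1):
                length = sig.size // s
                if length < min_len:
                    continue
                coarse = sig[: length * s].reshape(length, s).mean(axis=1)
                per_scale[e, s - 1] = sample_entropy(coarse, m=m, r=tol)
        with np.errstate(invalid="ignore"):
            valid = np.any(np.isfinite(per_scale), axis=0)
            out[c, valid] = np.nanmean(per_scale[:, valid], axis=0)
    return out


def _spline_gh(cosang: np.ndarray, m: int, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Perrin spherical-spline G and H kernel matrices via Legendre sums."""
    g = np.zeros_like(cosang)
    h = np.zeros_like(cosang)
    for n in range(1, n_terms + 1):
        pn = eval_legendre(n, cosang)
        g += (2 * n + 1) / (n * (n + 1)) ** m * pn
        h += -(2 * n + 1) / (n * (n + 1)) ** (m - 1) * pn
    return g / (4 * np.pi), h / (4 * np.pi)


def surface_laplacian(
    eeg: EpochedEEG, m: int = 4, n_legendre: int = 10, reg: float = 1e-5
) -> EpochedEEG:
    """Spherical-spline surface Laplacian (current-source-density estimate).

    Reference-free by construction: adding a constant to all channels
    leaves the output unchanged, and a spatially uniform field maps to zero.
    """
    if eeg.n_channels < 8:
        raise ValueError("surface Laplacian needs at least 8 channels")
    pos = eeg.layout.positions
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(len(pos), dtype=bool)] > 1 - 1e-12):
        raise ValueError("duplicate channel positions")
    g, h = _spline_gh(cosang, m, n_legendre)
    gs = g + reg * np.eye(len(pos))
    gi = np.linalg.inv(gs)
    ones = np.ones((len(pos), 1))
    denom = float((ones.T @ gi @ ones).item())
    # c = Gi (v - c0 1), c0 = (1' Gi v) / (1' Gi 1); laplacian = H c
    operator = h @ (gi - (gi @ ones @ ones.T @ gi) / denom)
    out = np.einsum("ij,ejk->eik", operator, eeg.data)
    return EpochedEEG(
        participant_id=eeg.participant_id,
        sampling_rate=eeg.sampling_rate,
        data=out,
        layout=eeg.layout,
    )


def ispc(
    eeg: EpochedEEG, band: str, pairs: list[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Inter-site phase clustering per channel pair in one band.

    ISPC = |mean over time of exp(i (phi_a - phi_b))|, averaged over epochs.
    Expects Laplacian-transformed input for the canonical pipeline, but
    operates on any EpochedEEG.
    """
    centre, width = _band_centre_fwhm(band)
    analytic = _analytic_narrowband(eeg.data, eeg.sampling_rate, centre, width)
    mag = np.abs(analytic)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(mag > 0, analytic / mag, 0.0)
    # Resultant of phase differences for all pairs at once: per epoch (z z^H)/T
    r = np.abs(np.einsum("ecs,eds->ecd", z, z.conj())) / eeg.n_samples
    r_mean = r.mean(axis=0)
    idx = {name: i for i, name in enumerate(eeg.layout.names)}
    out = {}
    for a, b in pairs:
        out[(a, b)] = float(r_mean[idx[a], idx[b]])
    return out


def extract_participant_metrics(
    eeg: EpochedEEG,
    registry: VariableRegistry,
    grid: np.ndarray | None = None,
    mse_scales: int = 20,
) -> ParticipantMetrics:
    """Run all six metric families on one recording, ready for aggregation."""
    spectra = gaussian_narrowband_power(eeg, grid=grid)
    n_ch = eeg.n_channels
    exponent = np.empty(n_ch)
    offset = np.empty(n_ch)
    paf_f = np.empty(n_ch)
    paf_a = np.empty(n_ch)
    for c in range(n_ch):
        fit = fit_aperiodic(spectra.grid, spectra.absolute[c])
        exponent[c], offset[c] = fit.exponent, fit.offset
        paf = peak_alpha(spectra.grid, spectra.absolute[c], aperiodic=fit)
        paf_f[c], paf_a[c] = paf.frequency, paf.amplitude

    pac = {}
    for phase_band, amp_band in registry.pac_pairs:
        pac[f"{phase_band}->{amp_band}"] = pac_band_pair(eeg, phase_band, amp_band)

    mse = multiscale_entropy(eeg, n_scales=mse_scales)

    lap = surface_laplacian(eeg)
    pair_union: list[tuple[str, str]] = []
    seen = set()
    for pairs in registry.ispc_pairs.values():
        for p in pairs:
            if p not in seen and (p[1], p[0]) not in seen:
                seen.add(p)
                pair_union.append(p)
    ispc_values = {band: ispc(lap, band, pair_union) for band in registry.bands}

    return ParticipantMetrics(
        channel_names=list(eeg.layout.names),
        grid=spectra.grid,
        power_absolute=spectra.absolute,
        power_relative=spectra.relative,
        power_log=spectra.log,
        exponent=exponent,
        offset=offset,
        paf_frequency=paf_f,
        paf_amplitude=paf_a,
        pac=pac,
        mse=mse,
        ispc=ispc_values,
    )


def feature_table_from_recordings(
    recordings: dict[str, EpochedEEG],
    registry: VariableRegistry,
    grid: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Extract and aggregate all metric families into a feature table.

    One row per participant, columns in registry order.  This is the
    EEG-time-series route; for cohort-scale statistical experiments prefer
    :func:`eegbattery.cohort.simulate_feature_table`.
    """
    import pandas as pd

    from eegbattery.registry import aggregate

    rows = {}
    for pid, eeg in recordings.items():
        metrics = extract_participant_metrics(eeg, registry, grid=grid)
        rows[pid] = aggregate(metrics, registry)
    table = pd.DataFrame(rows).T
    table.index.name = "participant_id"
    return table.reset_index()
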