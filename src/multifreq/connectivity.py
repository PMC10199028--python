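"""Multi-frequency network construction from trial-epoched time series.

Intra-layer edges are time-frequency phase-locking values (PLV): the
across-trial consistency of the phase difference between two channels at
each time-frequency point, averaged over an analysis window and a frequency
band.  Inter-layer edges are direct phase-amplitude coupling (dPAC): the
normalized alignment of a high-frequency amplitude envelope at one channel
with a low-frequency phase at another, averaged over the window and over
the (phase band x amplitude band) grid.  Both are in [0, 1], so intra- and
inter-layer weights live on the same scale.

Phase and amplitude are extracted from a reduced-interference Rihaczek
(RID-Rihaczek) complex time-frequency distribution: the Rihaczek
distribution C(t, f) = x(t) X*(f) e^{-j 2 pi f t} filtered in the
ambiguity (doppler-lag) plane by a Choi-Williams kernel
exp(-(theta * tau)^2 / sigma) that suppresses oscillatory cross-terms
between well-separated signal components while leaving the auto-term
marginals (the theta = 0 and tau = 0 axes) untouched.

Memory note: the pairwise accumulators scale as channels^2 x window x
frequency bins; suitable for tens of channels at desk scale.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .network import MultilayerNetwork

__all__ = [
    "TrialEpochs",
    "BandSpec",
    "TFD",
    "load_epochs",
    "save_epochs",
    "rid_rihaczek",
    "tf_phase_difference",
    "plv",
    "intra_layer_weights",
    "amplitude_envelope",
    "low_freq_phase",
    "dpac",
    "inter_layer_weights",
    "build_network",
]

_MAG_EPS = 1e-12


@dataclasses.dataclass
class TrialEpochs:
    """Trial-epoched multichannel data: channels x samples x trials.

    ``t0`` is the time of the response (event) relative to epoch start, in
    seconds; analysis windows are specified relative to the response.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be channels x samples x trials")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[2] < 2:
            raise ValueError("PLV/dPAC need at least 2 trials")
        if self.channel_names is None:
            self.channel_names = [str(i) for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def save_epochs(epochs: TrialEpochs, path: str) -> None:
    """Write epochs as ``<base>.npy`` plus a ``<base>.manifest.yaml``
    sidecar (sampling rate, response time, channel labels)."""
    import yaml

    base = str(path).removesuffix(".npy")
    np.save(base + ".npy", epochs.data)
    manifest = {
        "fs": float(epochs.fs),
        "t0": float(epochs.t0),
        "channels": list(epochs.channel_names),
    }
    with open(base + ".manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_epochs(path: str) -> TrialEpochs:
    """Read a channels x samples x trials array saved by :func:`save_epochs`."""
    import yaml

    base = str(path).removesuffix(".npy")
    data = np.load(base + ".npy")
    with open(base + ".manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return TrialEpochs(
        data, float(manifest["fs"]), float(manifest["t0"]),
        [str(c) for c in manifest["channels"]],
    )


@dataclasses.dataclass
class BandSpec:
    """Ordered frequency bands (Hz) and an analysis window (s, response-relative).

    Defaults follow the conventional EEG bands theta 4-7, alpha 8-12,
    beta 13-30, gamma 31-100 Hz and a 25-75 ms post-response window.
    Band membership of a frequency bin is half-open: f_lo <= f < f_hi.
    """

    bands: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            "theta": (4.0, 7.0),
            "alpha": (8.0, 12.0),
            "beta": (13.0, 30.0),
            "gamma": (31.0, 100.0),
        }
    )
    window: tuple[float, float] = (0.025, 0.075)

    def __post_init__(self):
        items = list(self.bands.items())
        for lab, (lo, hi) in items:
            if not lo < hi:
                raise ValueError(f"band {lab!r}: need f_lo < f_hi")
        for (la, (lo_a, hi_a)), (lb, (lo_b, hi_b)) in zip(items, items[1:]):
            if hi_a > lo_b:
                raise ValueError(f"bands {la!r} and {lb!r} overlap or are unordered")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy t1 < t2")


@dataclasses.dataclass
class TFD:
    """Complex time-frequency distribution on a (times x freqs) grid.

    ``spectrum`` keeps the full DFT of the source signal so band-limited
    analytic components (envelopes, narrowband phases) can be reconstructed
    exactly from the distribution's spectral factor.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    spectrum: np.ndarray | None = None

    def band_bins(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Indices of frequency bins with f_lo <= f < f_hi."""
        return np.flatnonzero((self.freqs >= f_lo) & (self.freqs < f_hi))

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_analytic(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Band-limited analytic component of the source signal.

        Inverse DFT of the positive-frequency bins with f_lo <= f < f_hi
        (doubled, except DC), i.e. the frequency-constrained content of the
        signal as a complex narrowband oscillation a(t) e^{j phi(t)}.
        """
        if self.spectrum is None:
            raise ValueError("TFD carries no source spectrum")
        N = len(self.spectrum)
        freqs_full = np.fft.fftfreq(N) * (self.df * N)
        mask = np.zeros(N)
        sel = (freqs_full >= f_lo) & (freqs_full < f_hi)
        mask[sel] = 2.0
        if f_lo <= 0 < f_hi:
            mask[0] = 1.0
        if len(np.flatnonzero(sel)) == 0:
            raise ValueError(f"band [{f_lo}, {f_hi}) contains no frequency bins")
        return np.fft.ifft(self.spectrum * mask)


def _rid_tfd_matrix(x: np.ndarray, kernel_param: float) -> np.ndarray:
    """Full-grid RID-Rihaczek of a real signal; returns N x N complex.

    Rows index time, columns the full DFT frequency grid.  The ambiguity
    plane is reached by an FFT over time (doppler) and an inverse FFT over
    frequency (lag); the Choi-Williams kernel is applied on dimensionless
    doppler/lag grids theta, tau = fftfreq(N) and the transform inverted.
    ``kernel_param -> inf`` recovers the plain Rihaczek distribution.
    """
    N = len(x)
    X = np.fft.fft(x)
    t = np.arange(N)
    phase = np.exp(-2j * np.pi * np.outer(t, t) / N)
    C0 = np.outer(x, np.conj(X)) * phase
    if not np.isfinite(kernel_param):
        return C0
    amb = np.fft.fft(np.fft.ifft(C0, axis=1), axis=0)
    grid = np.fft.fftfreq(N)
    kernel = np.exp(-np.outer(grid, grid) ** 2 / kernel_param)
    return np.fft.fft(np.fft.ifft(amb * kernel, axis=0), axis=1)


DEFAULT_KERNEL = 1e-6


def rid_rihaczek(signal: np.ndarray, fs: float, kernel_param: float = DEFAULT_KERNEL) -> TFD:
    """RID-Rihaczek TFD of a 1-D real signal, positive-frequency half.

    Frequency resolution is fs / N; with 1-second epochs the grid is 1 Hz,
    so band sums count integer-Hz bins.  The default kernel width suppresses
    doppler content at f_d Hz beyond lags of about sqrt(kernel_param) * N *
    fs / f_d samples, so slow (theta-rate) temporal modulation survives
    while carrier-rate interference terms are strongly attenuated.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite samples")
    if kernel_param <= 0:
        raise ValueError("kernel_param must be positive")
    N = len(signal)
    C = _rid_tfd_matrix(signal, kernel_param)
    n_keep = N // 2 + 1
    freqs = np.arange(n_keep) * fs / N
    times = np.arange(N) / fs
    return TFD(C[:, :n_keep], times, freqs, spectrum=np.fft.fft(signal))


def tf_phase_difference(C_u: TFD, C_v: TFD) -> np.ma.MaskedArray:
    """Phase difference arg[C_u C_v* / (|C_u||C_v|)] in (-pi, pi].

    Bins where either distribution has (numerically) zero magnitude carry
    no phase; they are masked and excluded from downstream averages.
    """
    if C_u.values.shape != C_v.values.shape or not np.allclose(C_u.freqs, C_v.freqs):
        raise ValueError("TFDs must share time and frequency axes")
    cross = C_u.values * np.conj(C_v.values)
    scale = max(np.abs(C_u.values).max(), np.abs(C_v.values).max(), 1.0)
    mask = (np.abs(C_u.values) < _MAG_EPS * scale) | (
        np.abs(C_v.values) < _MAG_EPS * scale
    )
    return np.ma.MaskedArray(np.angle(cross), mask=mask)


def plv(phase_diffs: np.ndarray) -> np.ndarray:
    """Phase locking value across trials.

    ``phase_diffs`` has the trial axis first (K x ...); masked entries are
    excluded bin-wise.  PLV = |sum_k exp(j phi_k)| / K is in [0, 1].
    """
    phase_diffs = np.ma.asarray(phase_diffs)
    if phase_diffs.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials")
    vectors = np.ma.exp(1j * phase_diffs)
    count = np.maximum(vectors.count(axis=0), 1)
    return np.asarray(np.abs(vectors.sum(axis=0).filled(0.0)) / count)


def dpac(amplitudes: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Direct phase-amplitude coupling across trials, in [0, 1].

    ``amplitudes`` (nonnegative) and ``phases`` share shape with the trial
    axis first.  dPAC = |sum_k a_k exp(j phi_k)| / (sqrt(K) sqrt(sum_k
    a_k^2)), bounded by 1 via Cauchy-Schwarz with equality for constant
    amplitude and identical phases.  All-zero amplitudes give 0.
    """
    a = np.asarray(amplitudes, dtype=float)
    phi = np.asarray(phases, dtype=float)
    if a.shape != phi.shape:
        raise ValueError("amplitudes and phases must share shape (trial axis first)")
    K = a.shape[0]
    if K < 2:
        raise ValueError("dPAC needs at least 2 trials")
    num = np.abs(np.sum(a * np.exp(1j * phi), axis=0))
    den = np.sqrt(K) * np.sqrt(np.sum(a**2, axis=0))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def amplitude_envelope(C_u: TFD, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous amplitude envelope of the frequency-constrained content.

    The band-limited analytic component a(t) e^{j phi(t)} is reconstructed
    from the distribution's spectral factor over [f1, f2) and its magnitude
    returned — real and nonnegative, smooth at the modulation time scale.
    (The raw band-integrated bilinear marginal retains the real time factor
    |x(t)| and with it carrier-rate rectification ripple; the analytic
    reconstruction is the envelope the direct-PAC estimator expects.)
    """
    if band[0] >= band[1]:
        raise ValueError("empty band")
    return np.abs(C_u.band_analytic(*band))


def low_freq_phase(C_v: TFD, f_p: float, bandwidth: float | None = None) -> np.ma.MaskedArray:
    """Instantaneous low-frequency phase around f_p.

    Angle of the band-limited analytic component in [f_p - bandwidth/2,
    f_p + bandwidth/2) (a single DFT bin by default); advances at 2 pi f_p
    per second for a pure tone.  Masked where the component has
    (numerically) zero magnitude.
    """
    if bandwidth is None:
        bandwidth = C_v.df
    z = C_v.band_analytic(f_p - bandwidth / 2, f_p + bandwidth / 2 + 1e-9)
    mag = np.abs(z)
    scale = max(mag.max(), 1.0)
    return np.ma.MaskedArray(np.angle(z), mask=mag < _MAG_EPS * scale)


# ---------------------------------------------------------------------------
# Windowed band-averaged network weights
# ---------------------------------------------------------------------------


def _window_indices(epochs: TrialEpochs, window: tuple[float, float]) -> np.ndarray:
    t = np.arange(epochs.n_samples) / epochs.fs - epochs.t0
    idx = np.flatnonzero((t >= window[0]) & (t < window[1]))
    if len(idx) == 0:
        raise ValueError(f"window {window} contains no samples")
    return idx


def _tfd_stack(epochs: TrialEpochs, trial: int, kernel_param: float) -> tuple[np.ndarray, np.ndarray]:
    """TFDs of every channel for one trial: (channels, samples, freqs)."""
    N = epochs.n_samples
    n_keep = N // 2 + 1
    out = np.empty((epochs.n_channels, N, n_keep), dtype=complex)
    for ch in range(epochs.n_channels):
        out[ch] = _rid_tfd_matrix(epochs.data[ch, :, trial], kernel_param)[:, :n_keep]
    freqs = np.arange(n_keep) * epochs.fs / N
    return out, freqs


def intra_layer_weights(
    epochs: TrialEpochs,
    band: tuple[float, float],
    window: tuple[float, float],
    kernel_param: float = DEFAULT_KERNEL,
) -> np.ndarray:
    """Symmetric channel x channel PLV weights for one band, in [0, 1].

    w_uv = mean over window samples and band bins of PLV_uv(t, f).
    """
    w_idx = _window_indices(epochs, window)
    n_ch, K = epochs.n_channels, epochs.n_trials
    probe = rid_rihaczek(epochs.data[0, :, 0], epochs.fs, kernel_param)
    bins = probe.band_bins(*band)
    if len(bins) == 0:
        raise ValueError(f"band {band} contains no frequency bins")
    shape = (n_ch, n_ch, len(w_idx), len(bins))
    vec_sum = np.zeros(shape, dtype=complex)
    counts = np.zeros(shape, dtype=int)
    for k in range(K):
        tfds, _ = _tfd_stack(epochs, k, kernel_param)
        sub = tfds[:, w_idx][:, :, bins]  # channels x W x bins
        mags = np.abs(sub)
        scale = max(mags.max(), 1.0)
        valid = mags >= _MAG_EPS * scale
        unit = np.where(valid, sub / np.where(mags > 0, mags, 1.0), 0.0)
        vec_sum += unit[:, None] * np.conj(unit[None, :])
        counts += valid[:, None] & valid[None, :]
    plv_tf = np.abs(vec_sum) / np.maximum(counts, 1)
    W = plv_tf.mean(axis=(2, 3))
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def _pac_components(
    data: np.ndarray,
    fs: float,
    w_idx: np.ndarray,
    p_freqs: np.ndarray,
    a_freqs: np.ndarray,
    amp_bandwidth: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase unit vectors and amplitude envelopes for one trial.

    ``data`` is channels x samples.  Returns ``unit`` (channels, |W|,
    |p_freqs|) — e^{j phi(t, f_p)} of the single-bin analytic component,
    zero where the bin is empty — and ``amp`` (channels, |W|, |a_freqs|) —
    envelope of the analytic component in a band of width
    ``amp_bandwidth`` around each f_a.
    """
    n_ch, N = data.shape
    X = np.fft.fft(data, axis=1)
    t = np.arange(N) / fs
    p_bins = np.round(p_freqs * N / fs).astype(int)
    coef = X[:, p_bins]  # channels x fp
    mags = np.abs(coef)
    scale = max(np.abs(X).max(), 1.0)
    unit_coef = np.where(
        mags >= _MAG_EPS * scale, coef / np.where(mags > 0, mags, 1.0), 0.0
    )
    rot = np.exp(2j * np.pi * np.outer(t[w_idx], p_freqs))  # W x fp
    unit = unit_coef[:, None, :] * rot[None, :, :]
    freqs_full = np.fft.fftfreq(N) * fs
    amp = np.empty((n_ch, len(w_idx), len(a_freqs)))
    for j, fa in enumerate(a_freqs):
        lo, hi = fa - amp_bandwidth / 2, fa + amp_bandwidth / 2
        sel = (freqs_full >= lo) & (freqs_full < hi) & (freqs_full > 0)
        z = np.fft.ifft(X * (2.0 * sel)[None, :], axis=1)
        amp[:, :, j] = np.abs(z[:, w_idx])
    return unit, amp


def inter_layer_weights(
    epochs: TrialEpochs,
    band_phase: tuple[float, float],
    band_amp: tuple[float, float],
    window: tuple[float, float],
    amp_bandwidth: float | None = None,
    pac_direction: str = "mean",
) -> np.ndarray:
    """Channel x channel dPAC weights between a phase band and an amplitude
    band, in [0, 1].

    w_uv averages dPAC(f_p, f_a, t) over the window samples and the
    (phase band x amplitude band) frequency grid.  The low-frequency phase
    comes from the single-bin analytic component at f_p; the high-frequency
    envelope from the analytic component in a band of ``amp_bandwidth``
    around f_a (default: twice the phase band's upper edge, wide enough to
    carry modulation sidebands at any phase frequency in the band).
    ``pac_direction`` chooses how the two role assignments (phase at u /
    amplitude at v, and the reverse) combine into the undirected weight:
    "mean" (default), "max", or "phase_low" (phase strictly at the
    first/low-band argument).
    """
    if band_phase[0] >= band_amp[0]:
        raise ValueError("phase band must lie below the amplitude band")
    if pac_direction not in ("mean", "max", "phase_low"):
        raise ValueError(f"unknown pac_direction {pac_direction!r}")
    if amp_bandwidth is None:
        amp_bandwidth = 2.0 * band_phase[1]
    w_idx = _window_indices(epochs, window)
    n_ch, K, N = epochs.n_channels, epochs.n_trials, epochs.n_samples
    df = epochs.fs / N
    freqs = np.arange(N // 2 + 1) * df
    p_freqs = freqs[(freqs >= band_phase[0]) & (freqs < band_phase[1])]
    a_freqs = freqs[(freqs >= band_amp[0]) & (freqs < band_amp[1])]
    if len(p_freqs) == 0 or len(a_freqs) == 0:
        raise ValueError("empty phase or amplitude band grid")
    # num[u, v, t, fp, fa] = sum_k a_u(t, fa) exp(j phi_v(t, fp))
    num = np.zeros((n_ch, n_ch, len(w_idx), len(p_freqs), len(a_freqs)), dtype=complex)
    den = np.zeros((n_ch, len(w_idx), len(a_freqs)))
    for k in range(K):
        unit, amp = _pac_components(
            epochs.data[:, :, k], epochs.fs, w_idx, p_freqs, a_freqs, amp_bandwidth
        )
        num += amp[:, None, :, None, :] * unit[None, :, :, :, None]
        den += amp**2
    denom = np.sqrt(K) * np.sqrt(den)  # u, t, fa
    dpac_tf = np.zeros(num.shape)
    np.divide(
        np.abs(num),
        denom[:, None, :, None, :],
        out=dpac_tf,
        where=denom[:, None, :, None, :] > 0,
    )
    amp_u_phase_v = dpac_tf.mean(axis=(2, 3, 4))
    phase_u_amp_v = amp_u_phase_v.T
    if pac_direction == "phase_low":
        return phase_u_amp_v
    if pac_direction == "max":
        return np.maximum(amp_u_phase_v, phase_u_amp_v)
    return (amp_u_phase_v + phase_u_amp_v) / 2.0


def build_network(
    epochs: TrialEpochs,
    bands: BandSpec | None = None,
    kernel_param: float = DEFAULT_KERNEL,
    pac_direction: str = "mean",
) -> MultilayerNetwork:
    """Construct the multi-frequency multilayer network from epochs.

    One layer per band with PLV intra-layer weights; dPAC inter-layer
    weights between every lower band (phase) and higher band (amplitude).
    Deterministic given the epochs.
    """
    bands = bands or BandSpec()
    if pac_direction not in ("mean", "max", "phase_low"):
        raise ValueError(f"unknown pac_direction {pac_direction!r}")
    labels = list(bands.bands)
    L = len(labels)
    n_ch, K = epochs.n_channels, epochs.n_trials
    w_idx = _window_indices(epochs, bands.window)
    probe = rid_rihaczek(epochs.data[0, :, 0], epochs.fs, kernel_param)
    bins = {lab: probe.band_bins(*bands.bands[lab]) for lab in labels}
    for lab, b in bins.items():
        if len(b) == 0:
            raise ValueError(f"band {lab!r} contains no frequency bins")
    df = probe.df

    # single pass over trials: accumulate PLV unit-vector sums per band and
    # dPAC numerators/denominators per (phase band, amplitude band) pair
    plv_sum = {
        lab: np.zeros((n_ch, n_ch, len(w_idx), len(bins[lab])), dtype=complex)
        for lab in labels
    }
    plv_cnt = {
        lab: np.zeros((n_ch, n_ch, len(w_idx), len(bins[lab])), dtype=int)
        for lab in labels
    }
    band_freqs = {lab: probe.freqs[bins[lab]] for lab in labels}
    amp_bw = {
        (h, k): 2.0 * bands.bands[labels[h]][1] for h in range(L) for k in range(h + 1, L)
    }
    pac_num = {
        (h, k): np.zeros(
            (n_ch, n_ch, len(w_idx), len(bins[labels[h]]), len(bins[labels[k]])),
            dtype=complex,
        )
        for h in range(L)
        for k in range(h + 1, L)
    }
    pac_den = {
        (h, k): np.zeros((n_ch, len(w_idx), len(bins[labels[k]])))
        for h in range(L)
        for k in range(h + 1, L)
    }
    for trial in range(K):
        tfds, _ = _tfd_stack(epochs, trial, kernel_param)
        sub = tfds[:, w_idx]  # channels x W x freqs
        scale = max(np.abs(sub).max(), 1.0)
        for lab in labels:
            col = sub[:, :, bins[lab]]
            mags = np.abs(col)
            valid = mags >= _MAG_EPS * scale
            unit = np.where(valid, col / np.where(mags > 0, mags, 1.0), 0.0)
            plv_sum[lab] += unit[:, None] * np.conj(unit[None, :])
            plv_cnt[lab] += valid[:, None] & valid[None, :]
        for h in range(L):
            for k in range(h + 1, L):
                unit_p, amp = _pac_components(
                    epochs.data[:, :, trial],
                    epochs.fs,
                    w_idx,
                    band_freqs[labels[h]],
                    band_freqs[labels[k]],
                    amp_bw[(h, k)],
                )
                pac_num[(h, k)] += (
                    amp[:, None, :, None, :] * unit_p[None, :, :, :, None]
                )
                pac_den[(h, k)] += amp**2

    intra = {}
    for h, lab in enumerate(labels):
        plv_tf = np.abs(plv_sum[lab]) / np.maximum(plv_cnt[lab], 1)
        W = plv_tf.mean(axis=(2, 3))
        np.fill_diagonal(W, 0.0)
        intra[h] = (W + W.T) / 2.0
    inter = {}
    for h in range(L):
        for k in range(h + 1, L):
            denom = np.sqrt(K) * np.sqrt(pac_den[(h, k)])  # u x W x fa
            dpac_tf = np.zeros(pac_num[(h, k)].shape)
            np.divide(
                np.abs(pac_num[(h, k)]),
                denom[:, None, :, None, :],
                out=dpac_tf,
                where=denom[:, None, :, None, :] > 0,
            )
            amp_u_phase_v = dpac_tf.mean(axis=(2, 3, 4))  # amplitude at u
            phase_u_amp_v = amp_u_phase_v.T
            if pac_direction == "phase_low":
                inter[(h, k)] = phase_u_amp_v
            elif pac_direction == "max":
                inter[(h, k)] = np.maximum(amp_u_phase_v, phase_u_amp_v)
            else:
                inter[(h, k)] = (amp_u_phase_v + phase_u_amp_v) / 2.0
    return MultilayerNetwork(
        labels,
        [n_ch] * len(labels),
        intra,
        inter,
        {lab: list(epochs.channel_names) for lab in labels},
    )
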