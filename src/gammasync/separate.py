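"""Separation of multichannel LFPs into pathway-specific generators.

The recorded voltage at channel m is modelled as a linear mixture
u_m(t) = sum_n V_mn s_n(t) of N spatially fixed LFP-generators. After
zero-phase high-pass filtering and optional sharp-wave masking, the
channels are reduced by PCA and rotated to maximal independence by
FastICA, yielding the mixing matrix V (spatial voltage weights) and the
generator time courses s_n(t).

Normalisation convention: each generator's mixing column is scaled so
its maximum absolute weight is 1 (the activation is then the voltage at
the dominant site, microvolts) and the activation sign is chosen so
large excursions (waves) point up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import LfpRecording

__all__ = [
    "GeneratorDecomposition",
    "preprocess",
    "mask_sharp_waves",
    "decompose",
    "match_components",
]


@dataclass
class GeneratorDecomposition:
    """Mixing matrix, activations and variance bookkeeping of the
    separated LFP-generators, ordered by descending variance share."""

    mixing: np.ndarray  # channels x generators, uV per unit activation
    activations: np.ndarray  # generators x samples
    variance_share: np.ndarray  # per generator, fraction of LFP variance
    rate: float
    channel_meta: object = None
    labels: list[str] | None = None

    @property
    def n_generators(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self) -> np.ndarray:
        """V . s, the model LFP."""
        return self.mixing @ self.activations


def preprocess(rec: LfpRecording, highpass_hz: float = 1.0, order: int = 4) -> LfpRecording:
    """Zero-phase Butterworth high-pass to remove slow artifacts (1 Hz
    default cut-off); metadata and masks are preserved."""
    nyq = rec.rate / 2.0
    if highpass_hz >= nyq:
        raise ValueError(f"high-pass cutoff {highpass_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, highpass_hz, btype="highpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.voltages, axis=1)
    return LfpRecording(filtered, rec.rate, rec.channel_meta.copy(), list(rec.epoch_masks))


def mask_sharp_waves(
    trace: np.ndarray | LfpRecording,
    rate: float | None = None,
    mad_multiple: float = 5.0,
    lowpass_hz: float = 20.0,
    pad_s: float = 0.050,
    intervals: list[tuple[float, float]] | None = None,
) -> list[tuple[float, float]]:
    """Epoch masks around large slow (sharp-wave-like) deflections.

    Intervals where the <20 Hz low-passed envelope exceeds
    ``mad_multiple`` times its median absolute deviation are returned,
    padded by +/-50 ms and merged. Explicit ``intervals`` are honoured
    verbatim (detector skipped).
    """
    if intervals is not None:
        return list(intervals)
    if isinstance(trace, LfpRecording):
        rate = trace.rate
        x = trace.voltages.mean(axis=0)
    else:
        if rate is None:
            raise ValueError("rate required for a bare trace")
        x = np.asarray(trace, dtype=float)
    n = x.size
    if n == 0:
        return []
    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    lp = signal.sosfiltfilt(sos, x)
    env = np.abs(lp - np.median(lp))
    mad = np.median(np.abs(lp - np.median(lp)))
    thr = mad_multiple * mad
    above = env > thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    masks = []
    for i0, i1 in runs:
        lo = max(i0 / rate - pad_s, 0.0)
        hi = min((i1 + 1) / rate + pad_s, n / rate)
        if masks and lo <= masks[-1][1]:
            masks[-1] = (masks[-1][0], max(masks[-1][1], hi))
        else:
            masks.append((lo, hi))
    return masks


def decompose(
    rec: LfpRecording,
    n_components: int,
    seed: int = 0,
    channels: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> GeneratorDecomposition:
    """PCA dimension reduction followed by an ICA rotation.

    Masked samples are excluded from fitting; activations are then
    produced for the full record. Raises on rank-deficient input, naming
    the first deficient dimension.
    """
    from sklearn.decomposition import FastICA

    if channels is not None:
        rec = rec.subset(np.asarray(channels))
    if n_components > rec.n_channels:
        raise ValueError(
            f"n_components={n_components} exceeds channel count {rec.n_channels}"
        )
    x_full = rec.voltages  # channels x samples
    fit_idx = rec.unmasked_indices()
    x_fit = x_full[:, fit_idx]
    mean = x_fit.mean(axis=1, keepdims=True)
    xc = x_fit - mean

    sv = np.linalg.svd(xc, compute_uv=False)
    rel = sv / sv[0] if sv[0] > 0 else sv
    deficient = np.flatnonzero(rel < 1e-10)
    if deficient.size and deficient[0] < n_components:
        raise ValueError(
            f"rank-deficient input: dimension {int(deficient[0])} has negligible variance"
        )

    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    ica.fit(xc.T)
    mixing = ica.mixing_.copy()  # channels x components
    acts = ((x_full - mean).T @ np.linalg.pinv(mixing).T).T  # components x samples

    # normalisation: max |mixing weight| = 1; waves point up
    for j in range(n_components):
        m = np.max(np.abs(mixing[:, j]))
        if m > 0:
            mixing[:, j] /= m
            acts[j] *= m
        a = acts[j]
        sd = a.std()
        tail = a[np.abs(a) > 3.0 * sd]
        if tail.size and tail.mean() < 0:
            mixing[:, j] *= -1.0
            acts[j] *= -1.0

    total_var = float(np.sum(xc.var(axis=1)))
    share = np.array(
        [np.sum(mixing[:, j] ** 2) * acts[j, fit_idx].var() / total_var for j in range(n_components)]
    ) if total_var > 0 else np.zeros(n_components)

    order = np.argsort(share)[::-1]
    return GeneratorDecomposition(
        mixing=mixing[:, order],
        activations=acts[order],
        variance_share=share[order],
        rate=rec.rate,
        channel_meta=rec.channel_meta,
    )


@dataclass
class ComponentMatch:
    index_a: int
    index_b: int
    score: float


def match_components(
    a: GeneratorDecomposition, b: GeneratorDecomposition
) -> tuple[list[ComponentMatch], list[int], list[int]]:
    """Greedy maximum-correlation assignment between the depth-aligned
    spatial weight curves of two decompositions.

    Returns (matches, unmatched_a, unmatched_b); each match carries the
    Pearson correlation of the matched profiles. Profiles are compared on
    a common depth grid when channel counts differ (linear interpolation
    over relative depth).
    """
    pa = _depth_profiles(a)
    pb = _depth_profiles(b)
    corr = np.zeros((pa.shape[1], pb.shape[1]))
    for i in range(pa.shape[1]):
        for j in range(pb.shape[1]):
            corr[i, j] = np.corrcoef(pa[:, i], pb[:, j])[0, 1]
    matches: list[ComponentMatch] = []
    free_a = set(range(pa.shape[1]))
    free_b = set(range(pb.shape[1]))
    work = corr.copy()
    while free_a and free_b:
        i, j = np.unravel_index(np.nanargmax(work), work.shape)
        matches.append(ComponentMatch(int(i), int(j), float(corr[i, j])))
        free_a.discard(int(i))
        free_b.discard(int(j))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return matches, sorted(free_a), sorted(free_b)


def _depth_profiles(dec: GeneratorDecomposition, n_grid: int = 64) -> np.ndarray:
    """Mixing columns resampled onto a common relative-depth grid."""
    mix = dec.mixing
    meta = dec.channel_meta
    if meta is not None and "depth_um" in getattr(meta, "columns", []):
        depth = np.asarray(meta["depth_um"], dtype=float)
    else:
        depth = np.arange(mix.shape[0], dtype=float)
    span = depth.max() - depth.min()
    rel = (depth - depth.min()) / span if span > 0 else depth * 0.0
    grid = np.linspace(0.0, 1.0, n_grid)
    order = np.argsort(rel)
    out = np.column_stack(
        [np.interp(grid, rel[order], mix[order, j]) for j in range(mix.shape[1])]
    )
    return out
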