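"""Nonlinear complexity features for physiological time series.

Four regularity/complexity statistics are computed per channel window:

* **Approximate entropy (ApEn)** — likelihood that runs of ``m`` samples that
  are close (Chebyshev distance within a tolerance ``r``) remain close when
  extended to ``m + 1`` samples, with self-matches included.  Higher values
  indicate a more irregular, less predictable series.
* **Sample entropy (SaEn)** — the Richman–Moorman refinement of ApEn:
  self-matches are excluded and the logarithm is taken of the ratio of the
  aggregate match probabilities, ``-ln(A/B)``, removing ApEn's bias on short
  records.
* **Fuzzy entropy (FuEn)** — replaces the hard match threshold with a smooth
  Gaussian-like membership ``exp(-ln(2) * (D/r)^2)`` of the template distance
  ``D``, so the statistic varies continuously with the tolerance.
* **Wavelet packet entropy (WpEn)** — Shannon entropy of the normalized
  energy distribution over the terminal frequency bands of a wavelet packet
  decomposition; it quantifies how evenly signal energy is spread across the
  spectrum.

The tolerance ``r`` is taken as a fraction of the standard deviation of the
analysed window itself, which makes ApEn/SaEn/FuEn invariant under amplitude
scaling; WpEn is scale-invariant by construction because it only uses energy
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "EntropyParams",
    "ChannelFeatures",
    "FEATURE_NAMES",
    "approximate_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "wavelet_packet_entropy",
    "band_energies",
    "extract_channel_features",
]

#: Fixed feature order used everywhere downstream.
FEATURE_NAMES = ("apen", "saen", "fuen", "wpen")


@dataclass(frozen=True)
class EntropyParams:
    """Parameters shared by the four entropy features.

    Parameters
    ----------
    m : int
        Embedding (template) dimension for ApEn/SaEn/FuEn.  Values of 2-5
        are customary for biosignals; 2 is the default.
    r_frac : float
        Match tolerance as a fraction of the window's standard deviation
        (the customary range is 0.1-0.25; default 0.2).
    wavelet : str
        Wavelet family for the packet decomposition (PyWavelets name).
    depth : int
        Wavelet packet decomposition level; the terminal level has
        ``2**depth`` frequency bands.
    """

    m: int = 2
    r_frac: float = 0.2
    wavelet: str = "db4"
    depth: int = 3

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r_frac <= 0:
            raise ValueError(f"r_frac must be > 0, got {self.r_frac}")
        if self.depth < 1:
            raise ValueError(f"wavelet packet depth must be >= 1, got {self.depth}")


@dataclass(frozen=True)
class ChannelFeatures:
    """The four entropy values for one channel window, in fixed order."""

    channel: str
    apen: float
    saen: float
    fuen: float
    wpen: float

    def values(self) -> tuple[float, float, float, float]:
        return (self.apen, self.saen, self.fuen, self.wpen)


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def _chebyshev_matrix(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all m-length templates of x.

    Built incrementally from 1-D sample differences to avoid allocating an
    (n, n, m) array; memory is one (n, n) float matrix.
    """
    n = len(x) - m + 1
    d = np.abs(x[:n, None] - x[None, :n])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n, None] - x[None, k : k + n]), out=d)
    return d


def _resolve_r(x: np.ndarray, params: EntropyParams, r: float | None) -> float:
    return float(r) if r is not None else params.r_frac * float(np.std(x))


def approximate_entropy(
    x, params: EntropyParams | None = None, *, r: float | None = None
) -> float:
    """Approximate entropy of a series.

    Templates of length ``m`` are compared with the Chebyshev distance;
    matches (``d <= r``, self-matches included) are counted per template,
    log-averaged into ``phi_m``, and the statistic is
    ``phi_m - phi_{m+1}``.

    Parameters
    ----------
    x : array-like
        Sample series of length ``N >= m + 2``.
    params : EntropyParams, optional
        Provides ``m`` and ``r_frac``; defaults apply when omitted.
    r : float, optional
        Absolute tolerance overriding ``r_frac * std(x)``.

    Returns
    -------
    float
        Non-negative regularity statistic (0 for a perfectly regular,
        e.g. constant, series).
    """
    params = params or EntropyParams()
    x = _as_series(x)
    m = params.m
    if len(x) < m + 2:
        raise ValueError(f"series length {len(x)} < m + 2 = {m + 2}")
    rr = _resolve_r(x, params, r)
    if rr == 0.0:
        # zero-variance window: every template matches every other exactly
        return 0.0

    def phi(mm: int) -> float:
        d = _chebyshev_matrix(x, mm)
        c = np.count_nonzero(d <= rr, axis=1) / d.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(
    x, params: EntropyParams | None = None, *, r: float | None = None
) -> float:
    """Sample entropy (Richman–Moorman form).

    ``B`` is the mean fraction of template pairs within tolerance at
    dimension ``m`` (self-matches excluded, ``N - m`` templates), ``A`` the
    same at ``m + 1``; the statistic is ``-ln(A / B)``.

    Raises
    ------
    ValueError
        If no template pair matches at either dimension (the statistic is
        undefined) or the series is too short.
    """
    params = params or EntropyParams()
    x = _as_series(x)
    m = params.m
    if len(x) < m + 2:
        raise ValueError(f"series length {len(x)} < m + 2 = {m + 2}")
    rr = _resolve_r(x, params, r)
    if rr == 0.0:
        return 0.0
    n_templates = len(x) - m  # same count at both dimensions

    def match_fraction(mm: int) -> float:
        d = _chebyshev_matrix(x, mm)[:n_templates, :n_templates]
        matches = np.count_nonzero(d <= rr, axis=1) - 1  # drop self-match
        return float(np.mean(matches / (n_templates - 1)))

    b = match_fraction(m)
    a = match_fraction(m + 1)
    if a == 0.0 or b == 0.0:
        raise ValueError(
            "sample entropy undefined: no template matches within tolerance "
            f"(A={a}, B={b}); increase r or the series length"
        )
    return -math.log(a / b)


def fuzzy_entropy(
    x, params: EntropyParams | None = None, *, r: float | None = None
) -> float:
    """Fuzzy entropy with Gaussian-like membership.

    Each template pair contributes a graded membership
    ``exp(-ln(2) * (D/r)^2)`` of its Chebyshev distance ``D`` (so a pair at
    exactly ``D = r`` counts 0.5).  Per-template memberships are averaged
    excluding the self-pair, then across templates; the statistic is
    ``ln(phi_m) - ln(phi_{m+1})``.
    """
    params = params or EntropyParams()
    x = _as_series(x)
    m = params.m
    if len(x) < m + 2:
        raise ValueError(f"series length {len(x)} < m + 2 = {m + 2}")
    rr = _resolve_r(x, params, r)
    if rr == 0.0:
        return 0.0

    def phi(mm: int) -> float:
        d = _chebyshev_matrix(x, mm)
        a = np.exp(-math.log(2.0) * (d / rr) ** 2)
        # exclude the self-pair (membership 1 on the diagonal)
        c = (a.sum(axis=1) - 1.0) / (a.shape[0] - 1)
        return float(np.mean(c))

    return math.log(phi(m)) - math.log(phi(m + 1))


def band_energies(
    x, wavelet: str = "db4", depth: int = 3
) -> np.ndarray:
    """Energies of the terminal wavelet packet bands, in natural band order.

    Each energy is the sum of squared coefficients of one terminal node of a
    level-``depth`` wavelet packet decomposition (``2**depth`` bands).
    """
    x = _as_series(x)
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="symmetric", maxlevel=depth)
    nodes = wp.get_level(depth, order="natural")
    return np.array([float(np.sum(np.square(node.data))) for node in nodes])


def wavelet_packet_entropy(x, params: EntropyParams | None = None) -> float:
    """Shannon entropy of the normalized wavelet packet energy distribution.

    The series is decomposed to level ``depth``; band energies ``E_j`` are
    normalized to ``p_j = E_j / sum(E)`` and the statistic is
    ``-sum(p_j * ln p_j)`` with ``0 * ln 0 := 0``.  The result lies in
    ``[0, ln(2**depth)]``.

    Raises
    ------
    ValueError
        For an all-zero signal, whose energy distribution is undefined.
    """
    params = params or EntropyParams()
    e = band_energies(x, wavelet=params.wavelet, depth=params.depth)
    total = e.sum()
    if total == 0.0:
        raise ValueError("wavelet packet entropy undefined for an all-zero signal")
    p = e / total
    nz = p[p > 0.0]
    return float(-np.sum(nz * np.log(nz)))


def extract_channel_features(
    seg_channel, channel: str, params: EntropyParams | None = None
) -> ChannelFeatures:
    """Compute the four entropies of one channel window, in fixed order."""
    params = params or EntropyParams()
    try:
        return ChannelFeatures(
            channel=channel,
            apen=approximate_entropy(seg_channel, params),
            saen=sample_entropy(seg_channel, params),
            fuen=fuzzy_entropy(seg_channel, params),
            wpen=wavelet_packet_entropy(seg_channel, params),
        )
    except ValueError as exc:
        raise ValueError(f"channel {channel!r}: {exc}") from exc
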