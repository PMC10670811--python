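"""Single-scale entropy measures over dispersion patterns.

Dispersion entropy (DE) symbolizes a real-valued series by mapping each
sample through the normal cumulative distribution function (NCDF), quantizing
into ``c`` classes, and embedding the class labels into overlapping windows of
length ``m`` with delay ``d``.  The Shannon entropy of the resulting pattern
distribution is DE.  Cumulative residual dispersion entropy (CRDE) evaluates
the same pattern distribution through the cumulative residual entropy (CRE)
functional, which operates on the survival function ``1 - F`` and is therefore
sensitive to the *ordering* of patterns — two distributions that are
permutations of each other share the same DE but generally not the same CRDE.

All entropies are reported in nats (natural logarithm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

__all__ = [
    "DegenerateSeriesError",
    "SeriesTooShortError",
    "DispersionConfig",
    "PatternDistribution",
    "as_series",
    "ncdf_map",
    "map_to_classes",
    "extract_patterns",
    "pattern_rank",
    "pattern_distribution",
    "dispersion_entropy",
    "crde",
    "cumulative_residual_entropy_sample",
    "de_of_series",
    "crde_of_series",
]

#: Guard against pathological configurations: at most 10^6 distinct patterns.
MAX_PATTERNS = 10**6


class DegenerateSeriesError(ValueError):
    """The series is constant (zero variance) or too short to normalize."""


class SeriesTooShortError(ValueError):
    """The series does not admit at least two embedding windows."""


@dataclass(frozen=True)
class DispersionConfig:
    """Parameters of the dispersion-pattern construction.

    Parameters
    ----------
    m : int
        Embedding dimension (pattern length), ``m >= 2``.
    c : int
        Number of quantization classes, ``2 <= c <= 9``.
    d : int
        Time delay between the samples of an embedding window, ``d >= 1``.
    """

    m: int = 3
    c: int = 3
    d: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 2):
            raise ValueError(f"embedding dimension m must be an integer >= 2, got {self.m}")
        if not (isinstance(self.c, (int, np.integer)) and 2 <= self.c <= 9):
            raise ValueError(f"class count c must be an integer in [2, 9], got {self.c}")
        if not (isinstance(self.d, (int, np.integer)) and self.d >= 1):
            raise ValueError(f"time delay d must be an integer >= 1, got {self.d}")
        if self.m > 6 or self.c**self.m > MAX_PATTERNS:
            raise ValueError(
                f"configuration (m={self.m}, c={self.c}) exceeds the supported "
                f"pattern-space size (m <= 6 and c^m <= {MAX_PATTERNS})"
            )

    @property
    def n_patterns(self) -> int:
        """Total number of possible dispersion patterns, ``K = c**m``."""
        return int(self.c) ** int(self.m)

    @property
    def min_length(self) -> int:
        """Shortest analyzable series length, ``(m - 1) * d + 2``."""
        return (self.m - 1) * self.d + 2

    def n_windows(self, n: int) -> int:
        """Number of embedding windows in a series of length ``n``."""
        return n - (self.m - 1) * self.d

    def is_analyzable(self, n: int) -> bool:
        return self.n_windows(n) >= 2


@dataclass(frozen=True)
class PatternDistribution:
    """Relative frequencies over the ``c**m`` lexicographically ranked patterns.

    ``probabilities[k]`` is the relative frequency of the pattern with
    lexicographic rank ``k``; unobserved patterns carry probability zero.
    """

    probabilities: np.ndarray
    window_count: int
    config: DispersionConfig

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (self.config.n_patterns,):
            raise ValueError(
                f"expected {self.config.n_patterns} probability slots, got {p.shape}"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1 within 1e-12")

    def patterns(self) -> np.ndarray:
        """All possible patterns, shape ``(K, m)``, in lexicographic order."""
        cfg = self.config
        grids = np.meshgrid(*[np.arange(1, cfg.c + 1)] * cfg.m, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as (pattern, probability); pattern as a symbol string."""
        pats = ["".join(map(str, row)) for row in self.patterns()]
        return pd.DataFrame({"pattern": pats, "probability": self.probabilities})


def as_series(x) -> np.ndarray:
    """Validate and return a 1-D float array of finite values, length >= 1."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.reshape(-1)
    if arr.size < 1:
        raise ValueError("time series must contain at least one sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("time series contains NaN or infinite values")
    return arr


def ncdf_map(x) -> np.ndarray:
    """Map a series into (0, 1) through the normal CDF of its own statistics.

    Each sample is transformed as ``y_i = Phi((x_i - mu) / sigma)`` with
    ``mu`` the sample mean and ``sigma`` the sample standard deviation
    (``N - 1`` denominator).  The map is strictly increasing, so ranks and
    ties are preserved.

    Raises
    ------
    DegenerateSeriesError
        If the series is shorter than 2 samples or has zero variance.
    """
    arr = as_series(x)
    if arr.size < 2:
        raise DegenerateSeriesError("NCDF mapping requires at least 2 samples")
    sigma = arr.std(ddof=1)
    if sigma == 0:
        raise DegenerateSeriesError("NCDF mapping is undefined for a constant series")
    return norm.cdf((arr - arr.mean()) / sigma)


def map_to_classes(y, c: int) -> np.ndarray:
    """Quantize NCDF values in (0, 1) into integer classes ``1..c``.

    The class label is ``round(c * y + 0.5)`` with halves rounded away from
    zero, clamped to ``[1, c]`` — the standard dispersion-entropy assignment.
    """
    arr = np.asarray(y, dtype=float)
    if not (isinstance(c, (int, np.integer)) and c >= 2):
        raise ValueError(f"class count c must be an integer >= 2, got {c}")
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("NCDF values must lie strictly inside (0, 1)")
    # round-half-away-from-zero of the positive quantity c*y + 0.5
    labels = np.floor(c * arr + 1.0).astype(np.int64)
    return np.clip(labels, 1, c)


def extract_patterns(z, cfg: DispersionConfig) -> np.ndarray:
    """Embed a class series into its dispersion patterns.

    Returns an array of shape ``(N - (m - 1) * d, m)``; row ``i`` holds
    ``(z_i, z_{i+d}, ..., z_{i+(m-1)d})``.

    Raises
    ------
    SeriesTooShortError
        If fewer than two windows fit.
    """
    arr = np.asarray(z, dtype=np.int64)
    if arr.ndim != 1:
        arr = arr.reshape(-1)
    n_win = cfg.n_windows(arr.size)
    if n_win < 2:
        raise SeriesTooShortError(
            f"series of length {arr.size} admits {max(n_win, 0)} windows under "
            f"(m={cfg.m}, d={cfg.d}); at least 2 are required"
        )
    if np.any(arr < 1) or np.any(arr > cfg.c):
        raise ValueError(f"class labels must lie in [1, {cfg.c}]")
    span = (cfg.m - 1) * cfg.d + 1
    return sliding_window_view(arr, span)[:, :: cfg.d]


def pattern_rank(patterns, cfg: DispersionConfig) -> np.ndarray:
    """Lexicographic rank in ``[0, c**m - 1]`` of each pattern row."""
    pats = np.asarray(patterns, dtype=np.int64)
    weights = cfg.c ** np.arange(cfg.m - 1, -1, -1, dtype=np.int64)
    return (pats - 1) @ weights


def pattern_distribution(patterns, cfg: DispersionConfig) -> PatternDistribution:
    """Relative frequency of each possible pattern among the observed windows."""
    pats = np.asarray(patterns, dtype=np.int64)
    if pats.size == 0:
        raise ValueError("at least one dispersion pattern is required")
    counts = np.bincount(pattern_rank(pats, cfg), minlength=cfg.n_patterns)
    n_win = pats.shape[0]
    return PatternDistribution(counts / n_win, n_win, cfg)


def _neg_t_log_t(t: np.ndarray) -> np.ndarray:
    """Elementwise ``-t * ln(t)`` with the convention ``0 * ln 0 = 0``."""
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = -t[pos] * np.log(t[pos])
    return out


def dispersion_entropy(p: PatternDistribution) -> float:
    """Shannon entropy of the pattern distribution: ``-sum p ln p`` (nats).

    Lies in ``[0, ln(c**m)]``; invariant under any permutation of the
    probability vector.
    """
    return float(_neg_t_log_t(p.probabilities).sum())


def crde(p: PatternDistribution) -> float:
    """Cumulative residual dispersion entropy of the pattern distribution.

    With ``F_j`` the cumulative probability over patterns in lexicographic
    order, ``CRDE = -sum_j (1 - F_j) ln(1 - F_j)`` (nats).  All ``K = c**m``
    slots enter the sum, including unobserved patterns — their zero mass
    repeats the running survival value, which still contributes.  Bounded by
    ``(K - 1) / e``; order-sensitive, unlike :func:`dispersion_entropy`.
    """
    survival = 1.0 - np.cumsum(p.probabilities)
    # guard tiny negative round-off in the final survival values
    survival = np.clip(survival, 0.0, None)
    return float(_neg_t_log_t(survival).sum())


def cumulative_residual_entropy_sample(x) -> float:
    """Empirical cumulative residual entropy of a real-valued sample (nats).

    With order statistics ``x_(1) <= ... <= x_(N)`` and empirical survival
    ``(N - i)/N`` on the gap ``[x_(i), x_(i+1))``, returns

    ``-sum_{i=1}^{N-1} ((N - i)/N) * ln((N - i)/N) * (x_(i+1) - x_(i))``.

    Nonnegative; invariant under shifts of ``x`` and linear in positive
    rescaling.
    """
    arr = as_series(x)
    n = arr.size
    if n < 2:
        raise ValueError("empirical CRE requires at least 2 samples")
    xs = np.sort(arr)
    surv = (n - np.arange(1, n)) / n
    return float(np.sum(_neg_t_log_t(surv) * np.diff(xs)))


def _series_distribution(x, cfg: DispersionConfig) -> PatternDistribution:
    y = ncdf_map(x)
    z = map_to_classes(y, cfg.c)
    return pattern_distribution(extract_patterns(z, cfg), cfg)


def de_of_series(x, cfg: DispersionConfig) -> float:
    """Dispersion entropy of a raw series (NCDF map, quantize, embed, DE)."""
    return dispersion_entropy(_series_distribution(x, cfg))


def crde_of_series(x, cfg: DispersionConfig) -> float:
    """CRDE of a raw series (same symbolization pipeline as DE)."""
    return crde(_series_distribution(x, cfg))
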