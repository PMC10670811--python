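"""Sample entropy and multiscale sample entropy (MSE) baselines.

Sample entropy (SampEn) is ``-ln(A / B)`` where ``B`` counts pairs of
length-``m`` templates whose Chebyshev distance is within the tolerance and
``A`` counts the same for length ``m + 1``, self-matches excluded.  On short
series either count can be zero, leaving SampEn undefined — the mechanism
behind the "N/A" cells that MSE produces at large scale factors, and the
failure mode MCRDE is designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .entropy import SeriesTooShortError, as_series
from .multiscale import DEFAULT_SCALES, EntropyProfile, _multiscale

__all__ = ["SampEnConfig", "sample_entropy", "mse_profile"]


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy parameters.

    ``m_se`` is the template length; ``r`` the tolerance as a fraction of the
    standard deviation of the analyzed (coarse-grained) series.  Defaults
    ``m_se = 2, r = 0.15`` are the community standard for RR-interval data.
    """

    m_se: int = 2
    r: float = 0.15

    def __post_init__(self) -> None:
        if not (isinstance(self.m_se, (int, np.integer)) and self.m_se >= 1):
            raise ValueError(f"template length m_se must be an integer >= 1, got {self.m_se}")
        if not self.r > 0:
            raise ValueError(f"tolerance fraction r must be positive, got {self.r}")


def _match_pairs(x: np.ndarray, length: int, n_templates: int, tol: float) -> int:
    """Pairs (i < j) of length-``length`` templates within Chebyshev tol."""
    templates = sliding_window_view(x, length)[:n_templates]
    # pairwise Chebyshev distances as a running elementwise max over offsets
    dist = np.abs(templates[:, None, 0] - templates[None, :, 0])
    for k in range(1, length):
        np.maximum(dist, np.abs(templates[:, None, k] - templates[None, :, k]), out=dist)
    hits = dist <= tol
    return int((hits.sum() - n_templates) // 2)  # drop self-matches, count i < j


def sample_entropy(x, cfg: SampEnConfig = SampEnConfig()) -> Optional[float]:
    """Sample entropy of a series, or ``None`` where it is undefined.

    Both template lengths are counted over ``N - m_se`` windows — every
    length-``m_se`` template that admits a one-sample extension, and all of
    the length-``m_se + 1`` templates — so the conditional-probability ratio
    ``A / B`` compares like with like (the Richman–Moorman convention).
    Returns ``None`` when either match count is zero.
    """
    arr = as_series(x)
    n = arr.size
    if n <= cfg.m_se + 1:
        raise SeriesTooShortError(
            f"sample entropy with m_se={cfg.m_se} requires N > {cfg.m_se + 1}, got {n}"
        )
    tol = cfg.r * arr.std(ddof=0)
    n_templates = n - cfg.m_se  # both lengths yield exactly N - m_se windows
    b = _match_pairs(arr, cfg.m_se, n_templates, tol)
    if b == 0:
        return None
    a = _match_pairs(arr, cfg.m_se + 1, n_templates, tol)
    if a == 0:
        return None
    return float(-np.log(a / b))


def mse_profile(
    x,
    cfg: SampEnConfig = SampEnConfig(),
    s_max: int = DEFAULT_SCALES,
    *,
    subject_id: str = "",
    group: str = "",
) -> EntropyProfile:
    """Multiscale sample entropy over Costa coarse-graining.

    The tolerance is referenced to the standard deviation of each
    coarse-grained series, not the original.  Scales where the coarse series
    is too short, or where a match count vanishes, yield ``None``.
    """
    arr = as_series(x)

    def single_scale(coarse: np.ndarray) -> Optional[float]:
        try:
            return sample_entropy(coarse, cfg)
        except SeriesTooShortError:
            return None

    return _multiscale(
        arr,
        s_max,
        single_scale,
        "MSE",
        arr.size,
        {"m_se": cfg.m_se, "r": cfg.r},
        subject_id,
        group,
    )
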