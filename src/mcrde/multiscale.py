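"""Coarse-graining and multiscale entropy profiles (MCRDE, MDE).

The multiscale procedure averages the series over non-overlapping windows of
length ``s`` (Costa coarse-graining, trailing remainder discarded) and
evaluates a single-scale entropy on each coarse-grained series for
``s = 1..s_max``.  A scale at which the entropy cannot be computed — the
coarse series is too short for the embedding, or has zero variance — is
recorded as an explicit undefined value (``None``), mirroring the "N/A"
cells of group-comparison tables, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .entropy import (
    DegenerateSeriesError,
    DispersionConfig,
    SeriesTooShortError,
    as_series,
    crde,
    dispersion_entropy,
    extract_patterns,
    map_to_classes,
    pattern_distribution,
)

__all__ = [
    "EntropyProfile",
    "coarse_grain",
    "mcrde_profile",
    "mde_profile",
    "dispersion_profiles",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = 25


@dataclass(frozen=True)
class EntropyProfile:
    """Per-scale entropy values for scales ``1..s_max``.

    ``values[s - 1]`` holds the entropy at scale ``s`` or ``None`` where it
    is undefined.  ``params`` snapshots the configuration the profile was
    computed under; ``n`` is the original series length.
    """

    method: str
    values: tuple
    n: int
    params: Mapping = field(default_factory=dict)
    subject_id: str = ""
    group: str = ""

    @property
    def s_max(self) -> int:
        return len(self.values)

    def value(self, s: int) -> Optional[float]:
        if not 1 <= s <= self.s_max:
            raise IndexError(f"scale {s} outside 1..{self.s_max}")
        return self.values[s - 1]

    @property
    def defined_mask(self) -> np.ndarray:
        return np.array([v is not None for v in self.values])

    def as_array(self) -> np.ndarray:
        """Values as a float array with ``NaN`` marking undefined scales."""
        return np.array(
            [np.nan if v is None else v for v in self.values], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"scale": np.arange(1, self.s_max + 1), "value": self.as_array()}
        )
        frame["method"] = self.method
        for key, val in self.params.items():
            frame[key] = val
        frame["N"] = self.n
        return frame

    def to_csv(self, path_or_buf) -> None:
        # %.17g guarantees float64 round-trips exactly through the CSV
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "EntropyProfile":
        frame = pd.read_csv(path_or_buf, float_precision="round_trip")
        frame = frame.sort_values("scale")
        values = tuple(
            None if np.isnan(v) else float(v) for v in frame["value"].to_numpy()
        )
        meta_cols = [
            col for col in frame.columns if col not in ("scale", "value", "method", "N")
        ]
        params = {col: frame[col].iloc[0] for col in meta_cols}
        return cls(
            method=str(frame["method"].iloc[0]),
            values=values,
            n=int(frame["N"].iloc[0]),
            params=params,
        )


def coarse_grain(x, s: int) -> np.ndarray:
    """Average ``x`` over non-overlapping windows of length ``s``.

    Returns ``floor(N / s)`` window means; the trailing ``N mod s`` samples
    are discarded.  ``s = 1`` returns a value-identical copy of the input.
    """
    arr = as_series(x)
    if not (isinstance(s, (int, np.integer)) and s >= 1):
        raise ValueError(f"scale factor must be an integer >= 1, got {s}")
    n_win = arr.size // s
    if n_win < 1:
        raise SeriesTooShortError(
            f"scale {s} leaves no complete window in a series of length {arr.size}"
        )
    return arr[: n_win * s].reshape(n_win, s).mean(axis=1)


def _multiscale(
    x,
    s_max: int,
    single_scale: Callable[[np.ndarray], Optional[float]],
    method: str,
    n: int,
    params: Mapping,
    subject_id: str = "",
    group: str = "",
) -> EntropyProfile:
    values = []
    for s in range(1, s_max + 1):
        try:
            coarse = coarse_grain(x, s)
            values.append(single_scale(coarse))
        except (SeriesTooShortError, DegenerateSeriesError):
            values.append(None)
    return EntropyProfile(
        method=method,
        values=tuple(values),
        n=n,
        params=dict(params),
        subject_id=subject_id,
        group=group,
    )


def _frozen_moments(arr: np.ndarray):
    """Mean and sd (N - 1 denominator) of the original series, or ``None``.

    The NCDF mapping of every coarse-grained series reuses the moments of the
    original series, the convention of standard multiscale dispersion
    entropy: coarse-graining shrinks the variance, and renormalizing at each
    scale would mask exactly the loss of amplitude structure that the
    multiscale profile is meant to expose (for white noise it flattens the
    characteristic decay of the profile almost completely).
    """
    if arr.size < 2:
        return None
    sd = arr.std(ddof=1)
    if sd == 0:
        return None
    return arr.mean(), sd


def _coarse_distribution(
    coarse: np.ndarray, cfg: DispersionConfig, mu: float, sd: float
):
    if coarse.std(ddof=0) == 0:
        raise DegenerateSeriesError("coarse-grained series is constant")
    y = norm.cdf((coarse - mu) / sd)
    z = map_to_classes(y, cfg.c)
    return pattern_distribution(extract_patterns(z, cfg), cfg)


def _dispersion_multiscale(x, cfg, s_max, stat, method, subject_id, group):
    arr = as_series(x)
    moments = _frozen_moments(arr)
    params = {"m": cfg.m, "c": cfg.c, "d": cfg.d}
    if moments is None:  # constant or single-sample input: undefined everywhere
        return EntropyProfile(method, (None,) * s_max, arr.size, params,
                              subject_id, group)
    mu, sd = moments
    return _multiscale(
        arr,
        s_max,
        lambda coarse: stat(_coarse_distribution(coarse, cfg, mu, sd)),
        method,
        arr.size,
        params,
        subject_id,
        group,
    )


def mcrde_profile(
    x,
    cfg: DispersionConfig = DispersionConfig(),
    s_max: int = DEFAULT_SCALES,
    *,
    subject_id: str = "",
    group: str = "",
) -> EntropyProfile:
    """Multiscale CRDE: CRDE of the coarse-grained series at each scale.

    The NCDF normalization is frozen at the mean and standard deviation of
    the original series (see :func:`_frozen_moments`); at scale 1 the profile
    equals ``crde_of_series`` exactly.  Scales where the coarse series is
    constant or too short for the embedding yield ``None``.
    """
    return _dispersion_multiscale(x, cfg, s_max, crde, "MCRDE", subject_id, group)


def mde_profile(
    x,
    cfg: DispersionConfig = DispersionConfig(),
    s_max: int = DEFAULT_SCALES,
    *,
    subject_id: str = "",
    group: str = "",
) -> EntropyProfile:
    """Multiscale dispersion entropy: DE of each coarse-grained series."""
    return _dispersion_multiscale(
        x, cfg, s_max, dispersion_entropy, "MDE", subject_id, group
    )


def dispersion_profiles(
    x,
    cfg: DispersionConfig = DispersionConfig(),
    s_max: int = DEFAULT_SCALES,
) -> tuple:
    """Compute the (MDE, MCRDE) profile pair sharing one symbolization pass.

    Both measures consume the same per-scale pattern distribution, so
    computing them together halves the work of ensemble experiments.
    """
    arr = as_series(x)
    params = {"m": cfg.m, "c": cfg.c, "d": cfg.d}
    moments = _frozen_moments(arr)
    if moments is None:
        empty = (None,) * s_max
        return (
            EntropyProfile("MDE", empty, arr.size, params),
            EntropyProfile("MCRDE", empty, arr.size, params),
        )
    mu, sd = moments
    de_vals, crde_vals = [], []
    for s in range(1, s_max + 1):
        try:
            coarse = coarse_grain(arr, s)
            dist = _coarse_distribution(coarse, cfg, mu, sd)
            de_vals.append(dispersion_entropy(dist))
            crde_vals.append(crde(dist))
        except (SeriesTooShortError, DegenerateSeriesError):
            de_vals.append(None)
            crde_vals.append(None)
    return (
        EntropyProfile("MDE", tuple(de_vals), arr.size, params),
        EntropyProfile("MCRDE", tuple(crde_vals), arr.size, params),
    )
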