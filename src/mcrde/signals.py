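"""Seeded generators for the validation signals: white and 1/f (pink) noise.

White Gaussian noise (WGN) has a flat power spectrum and no temporal
correlation; pink noise has power spectral density proportional to 1/f and
long-range autocorrelation, the canonical "complex" benchmark.  A complexity
measure faithful to long-range structure should rank pink noise above WGN
across coarse-graining scales.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["generate_wgn", "generate_pink", "ensemble", "write_series", "read_series"]


def _validate_n(n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"signal length must be an integer >= 2, got {n}")


def generate_wgn(n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. standard normal samples; deterministic under ``seed``."""
    _validate_n(n)
    return np.random.default_rng(seed).standard_normal(n)


def generate_pink(n: int, seed: int) -> np.ndarray:
    """Pink (1/f) noise by spectral synthesis; deterministic under ``seed``.

    A white Gaussian series is taken to the frequency domain, each positive
    frequency bin is scaled by ``1 / sqrt(f)`` (so power falls as 1/f), the
    zero-frequency term is removed, and the inverse transform is standardized
    to zero mean and unit variance.
    """
    _validate_n(n)
    rng = np.random.default_rng(seed)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    signal = np.fft.irfft(spectrum * scale, n)
    return (signal - signal.mean()) / signal.std(ddof=0)


_GENERATORS = {"wgn": generate_wgn, "pink": generate_pink}


def ensemble(kind: str, n: int, realizations: int, base_seed: int) -> Iterator[np.ndarray]:
    """Yield ``realizations`` independent signals; realization ``k`` uses
    seed ``base_seed + k``."""
    try:
        gen = _GENERATORS[kind.lower()]
    except KeyError:
        raise ValueError(f"unknown signal kind {kind!r}; expected 'wgn' or 'pink'")
    for k in range(realizations):
        yield gen(n, base_seed + k)


def write_series(path, values, fmt: str = "txt") -> None:
    """Write a series as plain text, one sample per line, or indexed CSV."""
    arr = np.asarray(values, dtype=float)
    if fmt == "txt":
        np.savetxt(path, arr, fmt="%.12g")
    elif fmt == "csv":
        pd.DataFrame({"index": np.arange(arr.size), "value": arr}).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'txt' or 'csv'")


def read_series(path) -> np.ndarray:
    """Read a series written by :func:`write_series` (either format)."""
    with open(path) as handle:
        first = handle.readline()
    if first.strip().startswith("index"):
        return pd.read_csv(path)["value"].to_numpy(dtype=float)
    return np.loadtxt(path, dtype=float).reshape(-1)
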