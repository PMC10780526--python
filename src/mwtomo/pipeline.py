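"""Preprocessing of raw multistatic signals into normalized network inputs.

Chain: the 16x16x5000 trace tensor is stacked transmitter-major into a
256x5000 signal map, decimated by 20 to 256x250, padded with six trailing
zero columns to 256x256, and per-row min-max normalized so each antenna
pair's trace spans [0, 1] regardless of its raw amplitude (distant pairs
are orders of magnitude weaker than adjacent ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigError
from .fdtd import SignalTensor


class ShapeError(ValueError):
    """Input array has the wrong shape for a pipeline stage."""


class DataError(ValueError):
    """Input array has non-finite values."""


@dataclass(frozen=True)
class InputMap:
    """Normalized 256x256 network input.

    Row ``n`` holds the (tx = n // 16, rx = n % 16) trace; every non-constant
    row attains 0 and 1 exactly; rows constant before normalization are all
    zero. Padding happens before normalization, so the trailing pad columns
    hold each row's normalized zero level (exactly 0 only when the raw row
    minimum is >= 0).
    """

    values: np.ndarray

    def channel_pair(self, row: int, n_antennas: int = 16) -> tuple[int, int]:
        """(transmitter, receiver) indices encoded by ``row``."""
        return divmod(row, n_antennas)


def stack_signals(tensor: SignalTensor | np.ndarray) -> np.ndarray:
    """(n_ant, n_ant, n_steps) -> (n_ant^2, n_steps), transmitter-major."""
    data = tensor.data if isinstance(tensor, SignalTensor) else np.asarray(tensor)
    if data.ndim != 3 or data.shape[0] != data.shape[1]:
        raise ShapeError(f"expected (n_ant, n_ant, n_steps), got {data.shape}")
    n_ant = data.shape[0]
    return data.reshape(n_ant * n_ant, data.shape[2])


def unstack_signals(stacked: np.ndarray, n_antennas: int = 16) -> np.ndarray:
    """Inverse of :func:`stack_signals`."""
    if stacked.ndim != 2 or stacked.shape[0] != n_antennas**2:
        raise ShapeError(f"expected ({n_antennas**2}, n_steps), got {stacked.shape}")
    return stacked.reshape(n_antennas, n_antennas, stacked.shape[1])


def downsample(signal_map: np.ndarray, rate: int, average: bool = False) -> np.ndarray:
    """Keep every ``rate``-th column starting at column 0 (pure decimation).

    ``average=True`` instead averages each block of ``rate`` columns
    (optional anti-alias mode, off by default).
    """
    if rate < 1:
        raise ConfigError("rate must be >= 1")
    if signal_map.shape[1] % rate != 0:
        raise ConfigError(
            f"{signal_map.shape[1]} columns not divisible by rate {rate}"
        )
    if average:
        n_out = signal_map.shape[1] // rate
        return signal_map.reshape(signal_map.shape[0], n_out, rate).mean(axis=2)
    return signal_map[:, ::rate]


def pad_columns(signal_map: np.ndarray, n_cols: int) -> np.ndarray:
    """Append ``n_cols`` all-zero trailing columns."""
    if n_cols < 0:
        raise ConfigError("n_cols must be >= 0")
    if n_cols == 0:
        return signal_map.copy()
    pad = np.zeros((signal_map.shape[0], n_cols), dtype=signal_map.dtype)
    return np.concatenate([signal_map, pad], axis=1)


def minmax_normalize(signal_map: np.ndarray) -> InputMap:
    """Per-row min-max feature scaling: X' = (X - Xmin) / (Xmax - Xmin).

    Rows with zero range (the 0/0 case) map to all-zero by convention.
    """
    x = np.asarray(signal_map, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("non-finite values in signal map")
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return InputMap(values=out)


def preprocess(
    tensor: SignalTensor | np.ndarray, rate: int = 20, n_pad: int = 6
) -> InputMap:
    """Full chain: stack -> downsample -> pad -> min-max normalize.

    16x16x5000 in, 256x256 out at the defaults. Stage failures are re-raised
    with the stage name.
    """
    stages = (
        ("stack", lambda t: stack_signals(t)),
        ("downsample", lambda m: downsample(m, rate)),
        ("pad", lambda m: pad_columns(m, n_pad)),
        ("normalize", lambda m: minmax_normalize(m)),
    )
    result = tensor
    for name, fn in stages:
        try:
            result = fn(result)
        except Exception as exc:
            raise type(exc)(f"preprocess stage '{name}': {exc}") from exc
    return result
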