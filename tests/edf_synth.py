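"""Minimal synthetic EDF writer for test fixtures.

Writes just enough of the EDF specification (fixed-width ASCII header +
16-bit little-endian data records) for EDF readers to load a small
multi-channel test signal. Only used to build throwaway fixtures in
temporary directories; not a general-purpose exporter.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_synthetic_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: int,
    labels: list[str],
) -> None:
    """Write channels x samples microvolt data as a one-second-record EDF."""
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    ns, n = data_uv.shape
    if ns != len(labels):
        raise ValueError("one label per channel required")
    if n % fs:
        pad = fs - n % fs
        data_uv = np.pad(data_uv, ((0, 0), (0, pad)), mode="edge")
        n = data_uv.shape[1]
    n_records = n // fs

    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("synthetic test subject", 80),
        _field("synthetic test recording", 80),
        _field("01.01.24", 8),
        _field("00.00.00", 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_field(lbl, 16) for lbl in labels),
        b"".join(_field("dry electrode", 80) for _ in labels),
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(str(phys_min), 8) for _ in labels),
        b"".join(_field(str(phys_max), 8) for _ in labels),
        b"".join(_field(str(dig_min), 8) for _ in labels),
        b"".join(_field(str(dig_max), 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(str(fs), 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])
    records = b"".join(
        digital[:, r * fs:(r + 1) * fs].tobytes()
        for r in range(n_records)
    )
    Path(path).write_bytes(header + sig + records)
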