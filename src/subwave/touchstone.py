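"""Minimal Touchstone v1 (.sNp) reader/writer for multiport S-parameters.

Real/imaginary (RI) format, frequency in Hz, one matrix row per output line,
row-major S11 S12 ... ordering.  The reader accepts any v1 frequency unit and
RI/MA/DB formats, which covers files exported by common VNA software.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["read_touchstone", "write_touchstone"]

_FREQ_UNIT = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def write_touchstone(path, frequencies: np.ndarray, s: np.ndarray) -> None:
    """Write an (F, N, N) S-parameter array as Touchstone v1, Hz / RI / 50 ohm."""
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    s = np.asarray(s, dtype=complex)
    if s.ndim != 3 or s.shape[0] != len(freqs) or s.shape[1] != s.shape[2]:
        raise ValueError("s must be (F, N, N)")
    n = s.shape[1]
    with open(path, "w") as fh:
        fh.write(f"! {n}-port S-parameters\n")
        fh.write("# Hz S RI R 50\n")
        for f, mat in zip(freqs, s):
            for i in range(n):
                lead = f"{f:.9e} " if i == 0 else " " * 16
                row = " ".join(f"{v.real:.9e} {v.imag:.9e}" for v in mat[i])
                fh.write(lead + row + "\n")


def read_touchstone(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a Touchstone v1 file; returns (frequencies_Hz (F,), s (F, N, N))."""
    name = str(path)
    try:
        n = int(name.lower().rsplit(".s", 1)[1].rstrip("p"))
    except (IndexError, ValueError):
        raise ValueError(f"cannot infer port count from extension of {name!r}")
    scale = 1e9
    fmt = "RI"
    numbers: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].upper().split()
                for t in toks:
                    if t in _FREQ_UNIT:
                        scale = _FREQ_UNIT[t]
                    if t in ("RI", "MA", "DB"):
                        fmt = t
                continue
            numbers.extend(float(t) for t in line.split())
    per_freq = 1 + 2 * n * n
    if len(numbers) % per_freq:
        raise ValueError(f"malformed Touchstone data in {name!r}")
    arr = np.asarray(numbers, dtype=float).reshape(-1, per_freq)
    freqs = arr[:, 0] * scale
    a = arr[:, 1::2]
    b = arr[:, 2::2]
    if fmt == "RI":
        vals = a + 1j * b
    elif fmt == "MA":
        vals = a * np.exp(1j * np.deg2rad(b))
    else:  # DB
        vals = 10.0 ** (a / 20.0) * np.exp(1j * np.deg2rad(b))
    s = vals.reshape(-1, n, n)
    return freqs, s
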