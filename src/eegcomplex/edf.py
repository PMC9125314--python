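"""Minimal EDF (European Data Format) reader/writer.

Supports the plain EDF profile this package needs: identical sampling rate on
every signal, 16-bit samples, physical dimension μV.  Written because no EDF
library is available in the target environment; the format is a fixed-layout
ASCII header followed by little-endian int16 data records, so a compact codec
is safe and round-trip tested.
"""

from __future__ import annotations

import numpy as np

from .core import FormatError

_HDR = 256  # bytes of fixed header; plus 256 per signal


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} longer than {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sfreq: float, channel_names) -> None:
    """Write (n_channels, n_samples) μV data as a single-record-per-second EDF."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise FormatError("channel name count does not match data rows")
    spr = int(round(sfreq))  # samples per 1-s record
    if abs(spr - sfreq) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_rec = n_samp // spr
    if n_rec * spr != n_samp:
        # pad the tail record with the edge value so duration survives rounding
        pad = (n_rec + 1) * spr - n_samp
        data = np.pad(data, ((0, 0), (0, pad)), mode="edge")
        n_rec += 1

    # per-channel physical scaling onto the int16 grid
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("synthetic", 80))
        fh.write(_field("synthetic", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(_HDR + 256 * n_ch), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_rec), 8))
        fh.write(_field("1", 8))  # record duration, seconds
        fh.write(_field(str(n_ch), 4))
        for name in channel_names:
            fh.write(_field(name, 16))
        for _ in range(n_ch):
            fh.write(_field("EEG", 80))
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for v in pmin:
            fh.write(_field(f"{v:.8g}"[:8], 8))
        for v in pmax:
            fh.write(_field(f"{v:.8g}"[:8], 8))
        fh.write(_field(str(dmin), 8) * n_ch)
        fh.write(_field(str(dmax), 8) * n_ch)
        for _ in range(n_ch):
            fh.write(_field("", 80))
        fh.write(_field(str(spr), 8) * n_ch)
        fh.write(_field("", 32) * n_ch)
        # records: per record, all samples of signal 1, then signal 2, ...
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF written by :func:`write_edf` (equal rates, uV signals)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        header_bytes = int(raw[184:192].decode("ascii").strip())
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        n_ch = int(raw[252:256].decode("ascii").strip())
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"not a parseable EDF header: {exc}") from exc

    # signal header blocks are laid out field-major
    pos = _HDR
    names = [raw[pos + i * 16 : pos + (i + 1) * 16].decode("ascii").strip() for i in range(n_ch)]
    pos += 16 * n_ch + 80 * n_ch  # skip transducer
    dims = [raw[pos + i * 8 : pos + (i + 1) * 8].decode("ascii").strip() for i in range(n_ch)]
    pos += 8 * n_ch
    pmin = np.array([float(raw[pos + i * 8 : pos + (i + 1) * 8]) for i in range(n_ch)])
    pos += 8 * n_ch
    pmax = np.array([float(raw[pos + i * 8 : pos + (i + 1) * 8]) for i in range(n_ch)])
    pos += 8 * n_ch
    dmin = np.array([float(raw[pos + i * 8 : pos + (i + 1) * 8]) for i in range(n_ch)])
    pos += 8 * n_ch
    dmax = np.array([float(raw[pos + i * 8 : pos + (i + 1) * 8]) for i in range(n_ch)])
    pos += 8 * n_ch + 80 * n_ch  # skip prefiltering
    spr = [int(raw[pos + i * 8 : pos + (i + 1) * 8]) for i in range(n_ch)]
    if len(set(spr)) != 1:
        raise FormatError("EDF reader requires equal sampling rates across signals")
    spr0 = spr[0]
    sfreq = spr0 / rec_dur
    for d in dims:
        if d.lower() not in ("uv", "µv", ""):
            raise FormatError(f"unsupported physical dimension {d!r} (expected uV)")

    body = np.frombuffer(raw[header_bytes:], dtype="<i2")
    expected = n_rec * n_ch * spr0
    if body.size < expected:
        raise FormatError("EDF data section truncated")
    body = body[:expected].reshape(n_rec, n_ch, spr0)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (body.transpose(1, 0, 2).reshape(n_ch, -1) - dmin[:, None]) * gain[:, None] + pmin[
        :, None
    ]
    return data, sfreq, names
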