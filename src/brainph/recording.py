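"""Multichannel recording container and file I/O.

A recording is a ``channels x samples`` float matrix with a sampling rate,
channel labels and an optional frequency-band tag.  Recordings round-trip
through two plain-text-friendly formats:

* a delimited numeric matrix (one row per channel) with a ``#`` header
  carrying the sampling rate and channel labels, and
* EDF (European Data Format), the field's standard interchange format for
  electrophysiology.  Writing uses a minimal built-in EDF encoder (16-bit
  quantisation, one data record per file); reading goes through :mod:`mne`
  when it is available and is only needed for EDF input.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MultichannelRecording",
    "read_delimited",
    "write_delimited",
    "read_edf",
    "write_edf",
]


@dataclass
class MultichannelRecording:
    """EEG-style signal block: ``data[i, t]`` is channel *i* at sample *t*."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray, band: str | None = None) -> "MultichannelRecording":
        return replace(self, data=np.asarray(data, dtype=float),
                       band=band if band is not None else self.band)


# ---------------------------------------------------------------------------
# Delimited text format
# ---------------------------------------------------------------------------

def write_delimited(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write one row per channel, tab-separated, with a ``#`` metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz\t{rec.sampling_rate!r}\n")
        fh.write("# channels\t" + "\t".join(rec.channel_labels) + "\n")
        if rec.band is not None:
            fh.write(f"# band\t{rec.band}\n")
        np.savetxt(fh, rec.data, delimiter="\t")
    return path


def read_delimited(path: str | Path, sampling_rate: float | None = None) -> MultichannelRecording:
    """Read a channels x samples matrix written by :func:`write_delimited`.

    Plain matrices without a metadata header are accepted, but then the
    sampling rate must be supplied by the caller.
    """
    path = Path(path)
    labels: list[str] = []
    band = None
    rate = sampling_rate
    body = io.StringIO()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                key = parts[0]
                if key == "sampling_rate_hz":
                    rate = float(parts[1])
                elif key == "channels":
                    labels = parts[1:]
                elif key == "band":
                    band = parts[1]
                continue
            if line.strip():
                try:
                    [float(tok) for tok in line.split()]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric row: {exc}") from exc
                body.write(line)
    if rate is None:
        raise ValueError(
            f"{path}: no sampling rate in header and none supplied; pass sampling_rate="
        )
    body.seek(0)
    data = np.loadtxt(body, ndmin=2)
    return MultichannelRecording(data, rate, labels or [], band)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write an EDF file with one data record spanning the whole recording.

    Signals are scaled to the full 16-bit integer range per channel, so a
    read-back agrees with the original to within one quantisation step of
    ``(max - min) / 65535`` per channel.
    """
    path = Path(path)
    ns = rec.n_channels
    n_samples = rec.n_samples
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # guard flat channels: EDF requires phys_max > phys_min
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    now = _dt.datetime(2000, 1, 1)
    header = "".join([
        "0".ljust(8),
        "X X X X".ljust(80),                      # patient id (anonymous)
        "Startdate X X X X".ljust(80),            # recording id
        now.strftime("%d.%m.%y"),
        now.strftime("%H.%M.%S"),
        str(256 + ns * 256).ljust(8),
        "".ljust(44),
        "1".ljust(8),                             # number of data records
        f"{rec.duration:.6g}"[:8].ljust(8),       # record duration (s)
        str(ns).ljust(4),
    ])
    sig_header = "".join([
        "".join(lab[:16].ljust(16) for lab in rec.channel_labels),
        "".join("".ljust(80) for _ in range(ns)),       # transducer
        "".join("uV".ljust(8) for _ in range(ns)),
        "".join(f"{v:.8g}"[:8].ljust(8) for v in phys_min),
        "".join(f"{v:.8g}"[:8].ljust(8) for v in phys_max),
        "".join("-32768".ljust(8) for _ in range(ns)),
        "".join("32767".ljust(8) for _ in range(ns)),
        "".join("".ljust(80) for _ in range(ns)),       # prefiltering
        "".join(str(n_samples).ljust(8) for _ in range(ns)),
        "".join("".ljust(32) for _ in range(ns)),
    ])
    scale = (phys_max - phys_min) / 65535.0
    digital = np.round((rec.data - phys_min[:, None]) / scale[:, None]) - 32768
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(sig_header.encode("ascii"))
        fh.write(digital.tobytes())
    return path


def read_edf(path: str | Path) -> MultichannelRecording:
    """Read an EDF recording.

    Uses :func:`mne.io.read_raw_edf` when mne is installed; otherwise falls
    back to a minimal reader sufficient for files written by
    :func:`write_edf` (single data record, 2-byte samples).
    """
    path = Path(path)
    try:
        import mne  # noqa: PLC0415 - heavy optional import
    except ImportError:
        return _read_edf_minimal(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    # mne converts EDF "uV"-dimensioned channels to volts; undo for symmetry
    data = data * 1e6
    return MultichannelRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _read_edf_minimal(path: Path) -> MultichannelRecording:
    with open(path, "rb") as fh:
        hdr = fh.read(256).decode("ascii")
        n_records = int(hdr[236:244])
        record_dur = float(hdr[244:252])
        ns = int(hdr[252:256])
        sig = fh.read(ns * 256).decode("ascii")
        labels = [sig[16 * i:16 * (i + 1)].strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        pmin = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        pmax = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        dmin = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns
        dmax = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
        off += 8 * ns + 80 * ns
        nsamp = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        chunks = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                raw = fh.read(2 * nsamp[i])
                chunks[i].append(np.frombuffer(raw, dtype="<i2").astype(float))
    scale = (pmax - pmin) / (dmax - dmin)
    data = np.vstack([np.concatenate(c) for c in chunks])
    data = (data - dmin[:, None]) * scale[:, None] + pmin[:, None]
    rate = nsamp[0] / record_dur
    return MultichannelRecording(data, rate, labels)
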