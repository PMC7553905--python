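"""Reading, writing and preprocessing of EEG recordings.

Preprocessing chain (order fixed, each step logged in provenance):
band-pass filter -> downsample -> bad-channel spherical-spline interpolation
-> average reference -> epoch extraction/concatenation.

On-disk formats are deliberately plain text:

* recording: header lines ``# sfreq=...``, ``# channels=a,b,c``, optional
  ``# epochs=s0:e0;s1:e1`` and ``# condition=...``, then one whitespace-
  separated row per channel, written with 17 significant digits so a
  write/read round-trip is bit-exact for float64;
* montage: one ``id x y z`` line per channel (unit-sphere coordinates);
* events: ``sample,tag`` per line.

EDF files are read through :mod:`mne`.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal, special

from .core import EEGRecording, EventList

__all__ = [
    "read_recording",
    "write_recording",
    "read_montage",
    "write_montage",
    "read_events",
    "write_events",
    "bandpass_filter",
    "downsample",
    "interpolate_bad_channels",
    "average_reference",
    "extract_epochs",
    "preprocess",
    "write_templates",
    "read_templates",
    "write_labels_rle",
    "read_labels_rle",
]


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def write_recording(path: str | Path, rec: EEGRecording) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sfreq={float(rec.sfreq)!r}\n")
        fh.write("# channels=" + ",".join(rec.ch_names) + "\n")
        fh.write("# epochs=" + ";".join(f"{a}:{b}" for a, b in rec.epochs) + "\n")
        if rec.condition:
            fh.write(f"# condition={rec.condition}\n")
        np.savetxt(fh, rec.data, fmt="%.17g")


def read_recording(
    path: str | Path,
    format: str = "auto",
    montage: str | Path | None = None,
) -> EEGRecording:
    """Read a recording from delimited text or EDF.

    ``format`` is ``"delimited"``, ``"edf"`` or ``"auto"`` (by suffix).
    ``montage`` optionally names an ``id x y z`` positions file; its channel
    count must match the data.
    """
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "delimited":
        rec = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if montage is not None:
        names, pos = read_montage(montage)
        if len(names) != rec.n_channels:
            raise ValueError(
                f"channel-count mismatch: montage has {len(names)} positions "
                f"for {rec.n_channels} channels"
            )
        rec.ch_names = list(names)
        rec.ch_pos = pos
    return rec


def _read_delimited(path: Path) -> EEGRecording:
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
    if "sfreq" not in header:
        raise ValueError(f"{path}: missing sampling rate in header")
    data = np.loadtxt(path, skiprows=n_header, ndmin=2)
    names = header.get("channels", "")
    ch_names = names.split(",") if names else None
    epochs = None
    if "epochs" in header and header["epochs"]:
        epochs = np.array(
            [[int(a), int(b)] for a, b in
             (part.split(":") for part in header["epochs"].split(";"))]
        )
    return EEGRecording(
        data, float(header["sfreq"]), ch_names=ch_names, epochs=epochs,
        condition=header.get("condition", ""),
        provenance=[f"read({path.name})"],
    )


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data, float(raw.info["sfreq"]), ch_names=list(raw.ch_names),
        provenance=[f"read({path.name})"],
    )


def write_montage(path: str | Path, ch_names: list[str], ch_pos: np.ndarray) -> None:
    with Path(path).open("w") as fh:
        for name, (x, y, z) in zip(ch_names, ch_pos):
            fh.write(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_montage(path: str | Path) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    pos: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, x, y, z = line.split()
        names.append(name)
        pos.append([float(x), float(y), float(z)])
    return names, np.asarray(pos)


def write_events(path: str | Path, events: EventList) -> None:
    with Path(path).open("w") as fh:
        for s, t in zip(events.samples, events.tags):
            fh.write(f"{s},{t}\n")


def read_events(path: str | Path) -> EventList:
    pairs: list[tuple[int, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        s, _, t = line.partition(",")
        pairs.append((int(s), t.strip()))
    return EventList.from_pairs(pairs)


def write_templates(path: str | Path, templates) -> None:
    """Templates as a delimited channels x K matrix with a map-id header."""
    with Path(path).open("w") as fh:
        fh.write("# maps=" + ",".join(str(i) for i in templates.ids) + "\n")
        np.savetxt(fh, templates.maps.T, fmt="%.17g")


def read_templates(path: str | Path):
    from .clustering import TemplateSet

    maps = np.loadtxt(path, comments="#", ndmin=2)
    return TemplateSet(maps.T, provenance=f"read({Path(path).name})")


def write_labels_rle(path: str | Path, seq) -> None:
    """Run-length encoded labels: ``start,end,map`` per line (0-based, half-open)."""
    with Path(path).open("w") as fh:
        fh.write("# epochs=" + ";".join(f"{a}:{b}" for a, b in seq.epochs) + "\n")
        fh.write(f"# sfreq={float(seq.sfreq)!r}\n")
        fh.write(f"# n_maps={seq.n_maps}\n")
        for map_id, s, e in seq.runs():
            fh.write(f"{s},{e},{map_id}\n")


def read_labels_rle(path: str | Path):
    from .backfit import LabelSequence

    header: dict[str, str] = {}
    runs: list[tuple[int, int, int]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
            continue
        if line.strip():
            s, e, m = (int(v) for v in line.split(","))
            runs.append((s, e, m))
    epochs = np.array(
        [[int(a), int(b)] for a, b in
         (part.split(":") for part in header["epochs"].split(";"))]
    )
    labels = np.zeros(epochs[-1, 1], dtype=int)
    for s, e, m in runs:
        labels[s:e] = m
    return LabelSequence(labels, epochs, float(header["sfreq"]), int(header["n_maps"]))


# --------------------------------------------------------------------------
# preprocessing steps
# --------------------------------------------------------------------------

def _per_epoch(rec: EEGRecording, fn) -> np.ndarray:
    """Apply ``fn(segment) -> segment`` independently to every epoch."""
    out = np.empty_like(rec.data)
    for a, b in rec.epochs:
        out[:, a:b] = fn(rec.data[:, a:b])
    return out


def bandpass_filter(rec: EEGRecording, f_lo: float, f_hi: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per epoch.

    Forward-backward filtering (``sosfiltfilt``) keeps topographies
    undistorted (no phase shift); epochs are filtered independently so no
    energy bleeds across concatenation boundaries.  The pass band also
    removes DC.
    """
    if not 0 < f_lo < f_hi < rec.sfreq / 2:
        raise ValueError("need 0 < f_lo < f_hi < Nyquist")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=rec.sfreq, output="sos")
    padlen = 3 * (2 * order + 1)
    if np.any(rec.epochs[:, 1] - rec.epochs[:, 0] <= padlen):
        raise ValueError("epoch shorter than the filter warm-up length")
    out = rec.copy_with(data=_per_epoch(rec, lambda seg: signal.sosfiltfilt(sos, seg, axis=1)))
    out.log(f"bandpass({f_lo},{f_hi},butter{order},zero-phase)")
    return out


def downsample(rec: EEGRecording, target_sfreq: float) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target_sfreq``, per epoch."""
    if target_sfreq > rec.sfreq:
        raise ValueError("target rate above the original rate")
    frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    pieces = []
    bounds = [0]
    for a, b in rec.epochs:
        seg = signal.resample_poly(rec.data[:, a:b], up, down, axis=1)
        pieces.append(seg)
        bounds.append(bounds[-1] + seg.shape[1])
    data = np.concatenate(pieces, axis=1)
    epochs = np.column_stack([bounds[:-1], bounds[1:]])
    out = rec.copy_with(data=data, epochs=epochs, sfreq=float(target_sfreq))
    out.log(f"downsample({rec.sfreq}->{target_sfreq})")
    return out


def _spherical_spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin g(x) = 1/(4pi) sum_n (2n+1) / (n(n+1))^m P_n(x)."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** m * special.eval_legendre(n, cosang)
    return g / (4 * np.pi)


def interpolate_bad_channels(
    rec: EEGRecording,
    bad: list[str],
    m: int = 4,
    reg: float = 1e-5,
    n_terms: int = 50,
) -> EEGRecording:
    """Replace bad channels by Perrin-type spherical-spline interpolation.

    Splines are fitted on the good channels' unit-sphere positions (spline
    order ``m=4``, Legendre series truncated at degree ``n_terms=50``,
    ridge ``reg=1e-5`` on the Gram diagonal) and evaluated at the bad
    positions.  Good channels are untouched.
    """
    if not bad:
        out = rec.copy_with()
        out.log("interpolate([])")
        return out
    if rec.ch_pos is None:
        raise ValueError("channel positions required for interpolation")
    unknown = sorted(set(bad) - set(rec.ch_names))
    if unknown:
        raise ValueError(f"unknown channel ids: {unknown}")
    if len(bad) >= rec.n_channels / 2:
        raise ValueError("more than half of the channels marked bad")
    bad_idx = np.array([rec.ch_names.index(b) for b in bad])
    good_idx = np.array([i for i in range(rec.n_channels) if i not in set(bad_idx)])
    pos = rec.ch_pos / np.linalg.norm(rec.ch_pos, axis=1, keepdims=True)
    pg, pb = pos[good_idx], pos[bad_idx]
    g_gg = _spherical_spline_g(np.clip(pg @ pg.T, -1, 1), m, n_terms)
    g_bg = _spherical_spline_g(np.clip(pb @ pg.T, -1, 1), m, n_terms)
    n_good = len(good_idx)
    # spline system with the constant term: [[G + reg*I, 1], [1^T, 0]]
    a = np.empty((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg + reg * np.eye(n_good)
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    a[n_good, n_good] = 0.0
    rhs = np.vstack([rec.data[good_idx], np.zeros(rec.n_times)])
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("ill-conditioned spline system; using least squares")
        sol = np.linalg.lstsq(a, rhs, rcond=None)[0]
    coeffs, const = sol[:n_good], sol[n_good]
    data = rec.data.copy()
    data[bad_idx] = g_bg @ coeffs + const
    out = rec.copy_with(data=data)
    out.log(f"interpolate({bad})")
    return out


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous channel mean (idempotent)."""
    out = rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))
    out.log("average_reference")
    return out


def extract_epochs(
    rec: EEGRecording,
    events: EventList | None,
    epoch_length_s: float,
    mode: str = "pre-event",
    count: int | None = None,
    seed: int = 0,
) -> EEGRecording:
    """Cut epochs of exactly ``epoch_length_s`` and concatenate them.

    ``mode="pre-event"`` takes the window *ending* at each event sample
    (e.g. the 30 s preceding each awakening).  ``mode="random"`` places
    ``count`` non-overlapping windows uniformly at random (seeded), sorted
    by onset.  Output epoch boundaries delimit the concatenated windows.
    """
    n = int(round(epoch_length_s * rec.sfreq))
    if mode == "pre-event":
        if events is None or len(events.samples) == 0:
            raise ValueError("pre-event mode needs events")
        events.validate(rec.n_times)
        starts = np.sort(events.samples - n)
        if np.any(starts < 0):
            raise ValueError("window extends before the recording start")
    elif mode == "random":
        if count is None:
            raise ValueError("random mode needs a count")
        if count * n > rec.n_times:
            raise ValueError(
                f"cannot place {count} non-overlapping epochs of {n} samples "
                f"in {rec.n_times} samples"
            )
        rng = np.random.default_rng(seed)
        free = rec.n_times - count * n
        gaps = np.sort(rng.integers(0, free + 1, size=count))
        starts = gaps + n * np.arange(count)
    else:
        raise ValueError("mode must be 'pre-event' or 'random'")
    pieces = [rec.data[:, s: s + n] for s in starts]
    data = np.concatenate(pieces, axis=1)
    epochs = np.array([[i * n, (i + 1) * n] for i in range(len(starts))])
    out = rec.copy_with(data=data, epochs=epochs)
    out.log(f"extract_epochs({mode},{epoch_length_s}s,n={len(starts)})")
    return out


def preprocess(
    rec: EEGRecording,
    band: tuple[float, float] = (1.0, 50.0),
    target_sfreq: float | None = 250.0,
    bad: list[str] | None = None,
) -> EEGRecording:
    """Standard chain: band-pass, downsample, interpolate, average-reference."""
    out = bandpass_filter(rec, *band)
    if target_sfreq is not None and target_sfreq < out.sfreq:
        out = downsample(out, target_sfreq)
    if bad:
        out = interpolate_bad_channels(out, bad)
    return average_reference(out)
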