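"""Session data model, file I/O, epoching and class balancing.

A *Recording* is one EEG session: a [n_channels x n_samples] microvolt
signal at a fixed sampling rate plus interval annotations marking ictal
(seizure) spans.  Recordings are cut into fixed-length *epochs*, the unit
of classification.  All times are seconds; intervals are half-open
[start, end); sample indices are 0-based.

Two on-disk session formats are supported: EDF / EDF+ (the clinical
standard for scalp EEG; a minimal reader/writer lives here because no EDF
library is bundled with the runtime) and an ``.npz`` fixture format used
for synthetic sessions.  Feature matrices travel in HDF5 containers.
"""

from __future__ import annotations

import csv
import os
import re
import warnings
import zipfile
from dataclasses import dataclass, field

import h5py
import numpy as np

SEIZURE = "seizure"
NORMAL = "normal"
UNLABELED = "unlabeled"

#: paper-style default montage: 10-20 system, 21 electrodes, 500 Hz
DEFAULT_FS = 500.0
DEFAULT_CHANNELS = (
    "Fp1 Fp2 F3 F4 C3 C4 P3 P4 O1 O2 "
    "F7 F8 T3 T4 T5 T6 Fz Cz Pz A1 A2"
).split()


class SchemaError(ValueError):
    """A file or container violates the expected layout or invariants."""


class FormatError(ValueError):
    """A file cannot be parsed under the named format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationInterval:
    """Labelled half-open time interval [start_s, end_s) within a session."""

    start_s: float
    end_s: float
    label: str = SEIZURE

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise SchemaError(
                f"annotation interval requires start < end, got "
                f"[{self.start_s}, {self.end_s})"
            )
        if self.label not in (SEIZURE, NORMAL):
            raise SchemaError(f"unknown annotation label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """One multichannel EEG session in microvolts."""

    subject_id: str
    session_id: str
    signal: np.ndarray              # [n_channels x n_samples], microvolts
    fs: float                       # Hz
    channel_names: list[str]
    annotations: list[AnnotationInterval] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise SchemaError("signal must be 2-D [n_channels x n_samples]")
        if not self.fs > 0:
            raise SchemaError("sampling rate must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} channels"
            )
        dur = self.duration_s
        for a in self.annotations:
            if a.start_s < 0 or a.end_s > dur + 1e-9:
                raise SchemaError(
                    f"annotation [{a.start_s}, {a.end_s}) outside session "
                    f"[0, {dur})"
                )
        _check_no_overlap(self.annotations)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def seizure_intervals(self) -> list[AnnotationInterval]:
        return [a for a in self.annotations if a.label == SEIZURE]


def _check_no_overlap(annotations):
    by_label: dict[str, list[AnnotationInterval]] = {}
    for a in annotations:
        by_label.setdefault(a.label, []).append(a)
    for label, items in by_label.items():
        items = sorted(items, key=lambda a: a.start_s)
        for prev, cur in zip(items, items[1:]):
            if cur.start_s < prev.end_s - 1e-9:
                raise SchemaError(
                    f"overlapping {label!r} annotations "
                    f"[{prev.start_s},{prev.end_s}) and "
                    f"[{cur.start_s},{cur.end_s})"
                )


@dataclass
class Epoch:
    """Fixed-length window of a recording; one classification example."""

    data: np.ndarray                # [n_channels x n_epoch_samples]
    start_s: float
    duration_s: float
    label: str = UNLABELED
    fs: float = DEFAULT_FS

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochSet:
    epochs: list[Epoch]
    subject_id: str = ""
    session_id: str = ""
    epoch_duration_s: float = 0.0
    overlap_fraction: float = 0.0

    def __len__(self):
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_recording(
    rec: Recording,
    epoch_duration_s: float,
    overlap_fraction: float = 0.0,
    seizure_overlap_threshold: float = 0.5,
) -> EpochSet:
    """Cut a recording into fixed-length epochs.

    Consecutive epochs advance by ``epoch_duration_s * (1 - overlap_fraction)``;
    a trailing partial window is dropped.  An epoch is labelled seizure iff at
    least ``seizure_overlap_threshold`` of its span lies within a seizure
    annotation (default: the 50% majority rule).
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if epoch_duration_s <= 0:
        raise ValueError("epoch_duration_s must be positive")
    n_len = int(round(epoch_duration_s * rec.fs))
    if n_len > rec.n_samples:
        raise ValueError(
            f"epoch of {epoch_duration_s}s ({n_len} samples) longer than "
            f"recording ({rec.n_samples} samples): empty epoch set"
        )
    step_s = epoch_duration_s * (1.0 - overlap_fraction)
    n_step = int(round(step_s * rec.fs))
    if n_step < 1:
        raise ValueError("overlap too large: step below one sample")

    seizure_ivals = rec.seizure_intervals()
    epochs = []
    start = 0
    while start + n_len <= rec.n_samples:
        t0 = start / rec.fs
        t1 = (start + n_len) / rec.fs
        cov = sum(
            max(0.0, min(t1, a.end_s) - max(t0, a.start_s))
            for a in seizure_ivals
        )
        label = SEIZURE if cov / epoch_duration_s >= seizure_overlap_threshold else NORMAL
        epochs.append(
            Epoch(
                data=rec.signal[:, start:start + n_len],
                start_s=t0,
                duration_s=epoch_duration_s,
                label=label,
                fs=rec.fs,
            )
        )
        start += n_step
    return EpochSet(
        epochs=epochs,
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        epoch_duration_s=epoch_duration_s,
        overlap_fraction=overlap_fraction,
    )


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def balance_dataset(seizure_vectors, normal_vectors, ratio: float = 3.0,
                    seed: int = 0):
    """Subsample normal vectors to ``ratio`` times the seizure-set size.

    Mirrors the hardware-era protocol of training on all seizure examples
    plus a random 3x-sized subset of the (overwhelmingly larger) normal
    pool.  Sampling is uniform without replacement and deterministic for a
    fixed seed.  If the normal pool is smaller than requested it is
    returned whole with a warning.
    """
    seizure_vectors = list(seizure_vectors)
    normal_vectors = list(normal_vectors)
    if len(seizure_vectors) == 0:
        raise ValueError("empty seizure set: nothing to balance against")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_want = int(round(ratio * len(seizure_vectors)))
    rng = np.random.default_rng(seed)
    if n_want >= len(normal_vectors):
        if n_want > len(normal_vectors):
            warnings.warn(
                f"normal pool ({len(normal_vectors)}) smaller than requested "
                f"{n_want}; returning all normal vectors"
            )
        idx = rng.permutation(len(normal_vectors))
    else:
        idx = rng.choice(len(normal_vectors), size=n_want, replace=False)
    return seizure_vectors, [normal_vectors[i] for i in idx]


# ---------------------------------------------------------------------------
# fixture (.npz) format + sidecar annotation CSV
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str, sidecar_csv: str | None = None):
    """Write a recording in the self-describing ``.npz`` fixture format.

    Annotations are embedded; if ``sidecar_csv`` is given they are also
    written as a ``start_s,end_s,label`` CSV (the sidecar convention used
    for formats that cannot carry annotations).
    """
    ann = rec.annotations
    np.savez_compressed(
        path,
        signal=rec.signal,
        fs=np.float64(rec.fs),
        channel_names=np.array(rec.channel_names),
        subject_id=np.str_(rec.subject_id),
        session_id=np.str_(rec.session_id),
        ann_start=np.array([a.start_s for a in ann], dtype=np.float64),
        ann_end=np.array([a.end_s for a in ann], dtype=np.float64),
        ann_label=np.array([a.label for a in ann]),
    )
    if sidecar_csv is not None:
        write_annotation_csv(ann, sidecar_csv)


def write_annotation_csv(annotations, path: str):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for a in annotations:
            w.writerow([a.start_s, a.end_s, a.label])


def read_annotation_csv(path: str) -> list[AnnotationInterval]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                start, end = float(row["start_s"]), float(row["end_s"])
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"malformed annotation row {row!r}") from exc
            out.append(AnnotationInterval(start, end, row.get("label", SEIZURE)))
    return out


def load_recording(path: str, format: str = None,
                   annotations_csv: str | None = None) -> Recording:
    """Load a session from EDF/EDF+ or the ``.npz`` fixture format.

    ``format`` is inferred from the extension when omitted.  For EDF,
    annotations come from the EDF+ annotation channel when present, or a
    sidecar CSV; a sidecar always takes precedence.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {"npz": "npz_fixture", "edf": "edf"}.get(ext.lstrip("."), None)
        if format is None:
            raise FormatError(f"cannot infer format from {path!r}")
    if format == "npz_fixture":
        rec = _load_npz(path)
    elif format == "edf":
        rec = _load_edf(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if annotations_csv is not None:
        rec = Recording(
            rec.subject_id, rec.session_id, rec.signal, rec.fs,
            rec.channel_names, read_annotation_csv(annotations_csv),
        )
    return rec


def _load_npz(path: str) -> Recording:
    try:
        with np.load(path, allow_pickle=False) as z:
            missing = {"signal", "fs", "channel_names"} - set(z.files)
            if missing:
                raise SchemaError(f"fixture missing datasets {sorted(missing)}")
            ann = [
                AnnotationInterval(float(s), float(e), str(l))
                for s, e, l in zip(
                    z.get("ann_start", []), z.get("ann_end", []),
                    z.get("ann_label", []),
                )
            ]
            return Recording(
                subject_id=str(z["subject_id"]) if "subject_id" in z else "",
                session_id=str(z["session_id"]) if "session_id" in z else "",
                signal=z["signal"],
                fs=float(z["fs"]),
                channel_names=[str(c) for c in z["channel_names"]],
                annotations=ann,
            )
    except (OSError, zipfile.BadZipFile, ValueError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise FormatError(f"cannot parse {path!r} as npz fixture: {exc}") from exc


# ---------------------------------------------------------------------------
# minimal EDF / EDF+ support
# ---------------------------------------------------------------------------

_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1e3, "v": 1e6}


def _load_edf(path: str) -> Recording:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError("truncated EDF header")

        def hfield(off, n):
            return hdr[off:off + n].decode("ascii", "replace").strip()

        try:
            n_records = int(hfield(236, 8))
            record_dur = float(hfield(244, 8))
            ns = int(hfield(252, 4))
        except ValueError as exc:
            raise FormatError(f"unparseable EDF header: {exc}") from exc
        patient = hfield(8, 80)
        recording_field = hfield(88, 80)

        sig_hdr = fh.read(ns * 256)
        if len(sig_hdr) < ns * 256:
            raise FormatError("truncated EDF signal header")

        # field offsets (bytes per signal): label 16, transducer 80,
        # phys_dim 8, phys_min 8, phys_max 8, dig_min 8, dig_max 8,
        # prefilter 80, samples_per_record 8, reserved 32
        offs = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        starts = np.cumsum([0] + offs[:-1])

        def column(idx, conv):
            base = int(starts[idx]) * ns
            width = offs[idx]
            out = []
            for i in range(ns):
                raw = sig_hdr[base + i * width: base + (i + 1) * width]
                out.append(conv(raw.decode("ascii", "replace").strip()))
            return out

        labels = column(0, str)
        phys_dim = column(2, str)
        try:
            phys_min = column(3, float)
            phys_max = column(4, float)
            dig_min = column(5, float)
            dig_max = column(6, float)
            spr = column(8, int)
        except ValueError as exc:
            raise FormatError(f"unparseable EDF signal header: {exc}") from exc

        data = fh.read()

    total_per_record = sum(spr)
    if n_records < 0:  # unknown; infer from file size
        n_records = len(data) // (2 * total_per_record)
    raw = np.frombuffer(data[: 2 * total_per_record * n_records], dtype="<i2")
    if raw.size < total_per_record * n_records:
        raise FormatError("EDF data shorter than header promises")
    raw = raw.reshape(n_records, total_per_record)

    is_ann = [l.strip().lower() == "edf annotations" for l in labels]
    sig_idx = [i for i in range(ns) if not is_ann[i]]
    if not sig_idx:
        raise SchemaError("EDF file contains no signal channels")
    if record_dur <= 0:
        raise SchemaError("EDF record duration must be positive")
    fs_all = {spr[i] / record_dur for i in sig_idx}
    if len(fs_all) != 1:
        raise SchemaError(f"mixed sampling rates {sorted(fs_all)} unsupported")
    fs = fs_all.pop()

    bounds = np.cumsum([0] + spr)
    channels, names = [], []
    for i in sig_idx:
        if dig_max[i] == dig_min[i] or phys_max[i] == phys_min[i]:
            raise SchemaError(
                f"channel {labels[i]!r} has degenerate calibration; "
                "unscaled digital EDF values are rejected"
            )
        unit = _UNIT_TO_UV.get(phys_dim[i].lower())
        if unit is None:
            raise SchemaError(
                f"channel {labels[i]!r} physical dimension {phys_dim[i]!r} "
                "not convertible to microvolts"
            )
        d = raw[:, bounds[i]:bounds[i + 1]].reshape(-1).astype(np.float64)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels.append(((d - dig_min[i]) * gain + phys_min[i]) * unit)
        names.append(labels[i])

    annotations = []
    for i in range(ns):
        if is_ann[i]:
            for rec_row in raw:
                tal_bytes = rec_row[bounds[i]:bounds[i + 1]].tobytes()
                annotations.extend(_parse_tal(tal_bytes))
    annotations = [a for a in annotations if a is not None]

    return Recording(
        subject_id=patient or "",
        session_id=recording_field or os.path.basename(path),
        signal=np.vstack(channels),
        fs=fs,
        channel_names=names,
        annotations=annotations,
    )


def _parse_tal(buf: bytes):
    """Parse EDF+ time-stamped annotation lists from one record.

    Events whose text mentions 'seiz' become seizure intervals; others are
    ignored (the data model only tracks ictal spans).
    """
    out = []
    for tal in buf.split(b"\x00"):
        if not tal or b"\x14" not in tal:
            continue
        head, *texts = tal.split(b"\x14")
        head = head.decode("ascii", "replace")
        m = re.match(r"([+-]\d+(?:\.\d+)?)(?:\x15(\d+(?:\.\d+)?))?", head)
        if not m:
            continue
        onset = float(m.group(1))
        duration = float(m.group(2)) if m.group(2) else 0.0
        text = " ".join(t.decode("utf-8", "replace") for t in texts if t)
        if duration > 0 and "seiz" in text.lower():
            out.append(AnnotationInterval(onset, onset + duration, SEIZURE))
    return out


def write_edf(rec: Recording, path: str, annotate: bool = True):
    """Write a minimal EDF+ file (16-bit, one data record per second).

    Fixture/tooling utility: enough of the standard for round-tripping
    synthetic sessions; not a general-purpose exporter.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = rec.n_samples // spr
    if n_records * spr != rec.n_samples:
        raise ValueError("EDF writer requires a whole number of 1 s records")

    ann_ns = 1 if annotate else 0
    ns = rec.n_channels + ann_ns
    phys_min, phys_max = -3276.8, 3276.7   # 0.1 uV resolution
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    header = b"".join(
        pad(v, n).encode("ascii") for v, n in [
            ("0", 8), (rec.subject_id, 80), (rec.session_id, 80),
            ("01.01.20", 8), ("00.00.00", 8), (256 * (1 + ns), 8),
            ("EDF+C" if annotate else "", 44), (n_records, 8), ("1", 8),
            (ns, 4),
        ]
    )

    labels = list(rec.channel_names) + (["EDF Annotations"] if annotate else [])
    ann_spr = 32  # 64 bytes per record for the TAL channel

    def col(values, n):
        return b"".join(pad(v, n).encode("ascii") for v in values)

    sig_hdr = b"".join([
        col(labels, 16),
        col([""] * ns, 80),
        col(["uV"] * rec.n_channels + [""] * ann_ns, 8),
        col([phys_min] * rec.n_channels + [-1] * ann_ns, 8),
        col([phys_max] * rec.n_channels + [1] * ann_ns, 8),
        col([dig_min] * ns, 8),
        col([dig_max] * ns, 8),
        col([""] * ns, 80),
        col([spr] * rec.n_channels + [ann_spr] * ann_ns, 8),
        col([""] * ns, 32),
    ])

    dig = np.clip(np.round((rec.signal - phys_min) * gain) + dig_min,
                  dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_records):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())
            if annotate:
                tal = f"+{r}\x14\x14\x00".encode("ascii")
                if r == 0:
                    for a in rec.seizure_intervals():
                        tal += (f"+{a.start_s:g}\x15{a.duration_s:g}"
                                f"\x14seizure\x14\x00").encode("ascii")
                tal = tal[: ann_spr * 2].ljust(ann_spr * 2, b"\x00")
                fh.write(np.frombuffer(tal, dtype="<i2").tobytes())


# ---------------------------------------------------------------------------
# HDF5 feature store
# ---------------------------------------------------------------------------

def feature_store_write(vectors, labels, metadata: dict, path: str):
    """Persist a feature matrix + labels + naming metadata to HDF5."""
    X = np.asarray(vectors)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise SchemaError("vectors must form a rectangular 2-D matrix")
    if y.shape[0] != X.shape[0]:
        raise SchemaError(
            f"{y.shape[0]} labels for {X.shape[0]} vectors"
        )
    metadata = dict(metadata or {})
    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=X)
        f.create_dataset("labels", data=y.astype("S16"))
        f.create_dataset(
            "channel_names",
            data=np.array(metadata.pop("channel_names", []), dtype=str_dt),
        )
        f.create_dataset(
            "feature_names",
            data=np.array(metadata.pop("feature_names", []), dtype=str_dt),
        )
        f.create_dataset(
            "epoch_duration_s",
            data=float(metadata.pop("epoch_duration_s", 0.0)),
        )
        for k, v in metadata.items():
            f.attrs[k] = v


def feature_store_read(path: str):
    with h5py.File(path, "r") as f:
        required = {"features", "labels", "channel_names", "feature_names",
                    "epoch_duration_s"}
        missing = required - set(f.keys())
        if missing:
            raise SchemaError(f"feature store missing datasets {sorted(missing)}")
        X = f["features"][...]
        y = np.array([s.decode() for s in f["labels"][...]])
        metadata = {
            "channel_names": [s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["channel_names"][...]],
            "feature_names": [s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["feature_names"][...]],
            "epoch_duration_s": float(f["epoch_duration_s"][()]),
        }
        metadata.update(dict(f.attrs))
    return X, y, metadata
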