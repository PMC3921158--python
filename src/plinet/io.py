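"""Readers and writers for the formats the pipeline touches.

* ASCII epoch files: one epoch per file, samples as rows and channels as
  columns in montage order, whitespace/tab/comma delimited, optional
  single header row of labels.
* EDF: reading via :mod:`mne`; writing via a minimal built-in 16-bit
  EDF encoder (enough to round-trip synthetic cohorts through standard
  EEG tooling).
* Results tables and cohort manifests as tab-separated text.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, MultichannelRecording
from .preprocess import DEFAULT_EPOCH_LENGTH

# ---------------------------------------------------------------------------
# ASCII epoch dialect


def write_ascii_epoch(path: str | Path, epoch: np.ndarray,
                      channels: tuple[str, ...] | None = None,
                      header: bool = True) -> Path:
    """Write one channels x samples epoch as samples-by-channels text."""
    path = Path(path)
    epoch = np.asarray(epoch, dtype=float)
    lines = []
    if header and channels:
        lines.append("\t".join(channels))
    for row in epoch.T:  # samples as rows
        lines.append("\t".join(format(v, ".17g") for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _detect_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    return None  # any whitespace


def read_ascii_epoch(path: str | Path, montage: Montage,
                     n_samples: int = DEFAULT_EPOCH_LENGTH) -> np.ndarray:
    """Read one epoch file into a channels x samples matrix in montage order.

    A non-numeric first row is treated as a header and skipped.  The
    column count must match the montage; any non-numeric cell is reported
    with its row and column.
    """
    path = Path(path)
    raw_lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw_lines:
        raise ValueError(f"{path}: empty file")
    delim = _detect_delimiter(raw_lines[0])
    start = 0
    try:
        [float(v) for v in raw_lines[0].split(delim)]
    except ValueError:
        start = 1  # header row
    rows: list[list[float]] = []
    for ri, ln in enumerate(raw_lines[start:], start=start + 1):
        cells = [c for c in ln.split(delim) if c != ""]
        row = []
        for ci, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {ri}, column {ci}"
                ) from None
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows with widths {sorted(widths)}")
    width = widths.pop()
    if width != montage.n_channels:
        raise ValueError(
            f"{path}: {width} columns but montage defines "
            f"{montage.n_channels} channels"
        )
    mat = np.array(rows, dtype=float).T  # -> channels x samples
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{path}: non-finite values present")
    if n_samples is not None and mat.shape[1] != n_samples:
        raise ValueError(
            f"{path}: {mat.shape[1]} sample rows, expected {n_samples}"
        )
    return mat


# ---------------------------------------------------------------------------
# EDF

_EDF_DIG_MAX = 32767


def write_edf(path: str | Path, recording: MultichannelRecording) -> Path:
    """Minimal EDF writer: one data record per second, 16-bit samples.

    The physical range per channel is set to its observed extrema, so
    round-trip error is bounded by the 16-bit quantization step.  The
    sample count is truncated to whole seconds.
    """
    path = Path(path)
    fs = recording.sfreq
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = recording.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = recording.data[:, : n_records * spr]
    nc = recording.n_channels

    def f(value: object, width: int) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    def edf_num(v: float) -> str:
        # widest representation that still fits the 8-char header field
        for p in range(7, 0, -1):
            s = format(float(v), f".{p}g")
            if len(s) <= 8:
                return s
        raise ValueError(f"cannot format {v} in 8 characters")

    # physical range per channel: observed extrema, widened a hair and
    # rounded outward through the 8-char header representation so the
    # scaling used for digitization matches the header exactly
    span = data.max(axis=1) - data.min(axis=1)
    pad = np.where(span > 0, span * 1e-6, 0.5)
    phys_min_s = [edf_num(v) for v in data.min(axis=1) - pad]
    phys_max_s = [edf_num(v) for v in data.max(axis=1) + pad]
    phys_min = np.array([float(s) for s in phys_min_s])
    phys_max = np.array([float(s) for s in phys_max_s])
    scale = (phys_max - phys_min) / (2 * _EDF_DIG_MAX)
    digital = np.clip(
        np.round((data - phys_min[:, None]) / scale[:, None]) - _EDF_DIG_MAX,
        -_EDF_DIG_MAX, _EDF_DIG_MAX,
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2000 X X X", 80),
        f(now.strftime("%d.%m.%y"), 8), f(now.strftime("%H.%M.%S"), 8),
        f(256 * (nc + 1), 8), f("", 44), f(n_records, 8), f(1, 8), f(nc, 4),
    ])
    fields = [
        ("".join(f(lab, 16).decode() for lab in recording.channels), None),
        ("".join(f("", 80).decode() for _ in range(nc)), None),
        # blank physical dimension: samples round-trip without unit rescaling
        ("".join(f("", 8).decode() for _ in range(nc)), None),
        ("".join(f(edf_num(v), 8).decode() for v in phys_min), None),
        ("".join(f(edf_num(v), 8).decode() for v in phys_max), None),
        ("".join(f(-_EDF_DIG_MAX, 8).decode() for _ in range(nc)), None),
        ("".join(f(_EDF_DIG_MAX, 8).decode() for _ in range(nc)), None),
        ("".join(f("", 80).decode() for _ in range(nc)), None),
        ("".join(f(spr, 8).decode() for _ in range(nc)), None),
        ("".join(f("", 32).decode() for _ in range(nc)), None),
    ]
    header += "".join(s for s, _ in fields).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within the record
    return path


def read_edf(path: str | Path, montage: Montage | None = None,
             ) -> MultichannelRecording:
    """Read an EDF file into a recording, optionally reordered to a montage.

    Channel labels are matched case-insensitively; missing montage
    channels raise with the absent labels listed.  EDF stores one rate
    per signal, and mixed rates are rejected.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    labels = tuple(raw.ch_names)
    sfreq = float(raw.info["sfreq"])
    if montage is None:
        return MultichannelRecording(data, sfreq, labels)
    lowered = [c.lower() for c in labels]
    idx = []
    missing = []
    for lab in montage.channels:
        try:
            idx.append(lowered.index(lab.lower()))
        except ValueError:
            missing.append(lab)
    if missing:
        raise ValueError(f"{path}: montage channels absent from EDF: {missing}")
    return MultichannelRecording(data[idx], sfreq, tuple(montage.channels))


# ---------------------------------------------------------------------------
# Results tables and cohort manifests

SUBJECT_COLUMNS = [
    "subject_id", "group", "band", "global_pli", "frontal_short",
    "posterior_short", "long_range", "clustering", "path_length",
    "clustering_norm", "path_length_norm", "small_world",
]
STATS_COLUMNS = ["band", "measure", "t", "df", "p", "eta_p2"]


def write_results(subject_rows: list[dict], stats_rows: list[dict],
                  out_dir: str | Path) -> tuple[Path, Path]:
    """Write the per-subject-per-band table and the group-stats table (TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subj = pd.DataFrame(subject_rows, columns=SUBJECT_COLUMNS)
    stats = pd.DataFrame(stats_rows, columns=STATS_COLUMNS)
    subj_path = out_dir / "subject_measures.tsv"
    stats_path = out_dir / "group_stats.tsv"
    subj.to_csv(subj_path, sep="\t", index=False, float_format="%.17g")
    stats.to_csv(stats_path, sep="\t", index=False, float_format="%.17g")
    return subj_path, stats_path


def write_manifest(entries: list[dict], path: str | Path) -> Path:
    """Cohort manifest: subject id, group, seed, file paths (TSV)."""
    path = Path(path)
    pd.DataFrame(entries).to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_connectivity_matrix(path: str | Path, values: np.ndarray,
                              channels: tuple[str, ...]) -> Path:
    """Square connectivity matrix as labelled TSV."""
    path = Path(path)
    pd.DataFrame(values, index=list(channels), columns=list(channels)).to_csv(
        path, sep="\t", float_format="%.17g")
    return path
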