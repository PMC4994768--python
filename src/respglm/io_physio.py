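"""Input/output for respiration traces, event tables and result tables.

Traces are uniformly sampled belt-transducer recordings; events are
(onset, condition) pairs on the same clock.  Two trace formats are
supported: plain delimited text (time, value columns, or a single value
column with an explicitly declared sampling rate) and BIDS-style
physiological recordings (``*_physio.tsv.gz`` plus a JSON sidecar with
``SamplingFrequency``, ``StartTime`` and ``Columns``).
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RespirationTrace",
    "EventTable",
    "RunConfig",
    "read_trace",
    "read_events",
    "write_trace",
    "write_results",
]


@dataclass(frozen=True)
class RespirationTrace:
    """Uniformly sampled belt-pressure signal.

    Parameters
    ----------
    values : ndarray
        Pressure samples, arbitrary units.
    fs : float
        Sampling frequency in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, ``n / fs`` seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class EventTable:
    """Event onsets (seconds, ascending) with one condition label each."""

    onsets: np.ndarray
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        conditions = tuple(str(c) for c in self.conditions)
        if len(conditions) != onsets.size:
            raise ValueError("onsets and conditions must have equal length")
        order = np.argsort(onsets, kind="stable")
        object.__setattr__(self, "onsets", onsets[order])
        object.__setattr__(self, "conditions", tuple(conditions[i] for i in order))

    def __len__(self) -> int:
        return self.onsets.size

    def subset(self, condition: str) -> np.ndarray:
        """Onsets belonging to one condition."""
        mask = np.array([c == condition for c in self.conditions])
        return self.onsets[mask]

    @property
    def condition_names(self) -> tuple[str, ...]:
        """Distinct condition labels, sorted."""
        return tuple(sorted(set(self.conditions)))


@dataclass
class RunConfig:
    """Run configuration; keys mirror the YAML config accepted by the CLI.

    All cut-off frequencies are in Hz and must lie strictly inside
    (0, fs/2) of the trace they are applied to; windows and the
    refractory period are in seconds.
    """

    preprocess_lp_cutoff_hz: float = 5.0
    preprocess_target_fs_hz: float = 10.0
    preprocess_zscore: bool = False
    detect_band_hz: tuple[float, float] = (0.01, 0.6)
    detect_median_win_s: float = 1.0
    detect_refractory_s: float = 1.0
    measures_band_hz: tuple[float, float] = (0.01, 1.0)
    measures_rll_window_s: float = 15.0
    measures_rpq_mode: str = "percent"  # "percent" or "ratio"
    basis_kind: str = "rp"
    basis_derivative: bool = False
    basis_duration_s: float = 30.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for band in (self.detect_band_hz, self.measures_band_hz):
            lo, hi = band
            if not (0 < lo < hi):
                raise ValueError(f"band edges must satisfy 0 < low < high, got {band}")
        if self.measures_rpq_mode not in ("percent", "ratio"):
            raise ValueError("rpq_mode must be 'percent' or 'ratio'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, object] = {}
        # accept either flat keys or nested sections (preprocess:, detect:, ...)
        for key, val in raw.items():
            if isinstance(val, dict):
                for sub, v in val.items():
                    flat[f"{key}_{sub}".replace("-", "_")] = v
            else:
                flat[key.replace("-", "_")] = v
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("detect_band_hz", "measures_band_hz"):
            if k in flat:
                flat[k] = tuple(flat[k])  # type: ignore[arg-type]
        return cls(**flat)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: Path) -> pd.DataFrame:
    """Delimiter-sniffing (comma/tab/whitespace) reader; '#' comments skipped."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                first = line
                break
    if "," in first:
        sep: str = ","
    elif "\t" in first:
        sep = "\t"
    else:
        sep = r"\s+"
    if sep == r"\s+":
        return pd.read_csv(path, sep=sep, comment="#", engine="python")
    return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")


def read_trace(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    t0: float = 0.0,
) -> RespirationTrace:
    """Read a respiration trace.

    Parameters
    ----------
    path : path
        For ``format="delimited"``: text with columns (time_s, value) or a
        single value column (then ``fs`` must be given).  For
        ``format="bids-physio"``: a ``*_physio.tsv.gz`` (or ``.tsv``) file
        whose JSON sidecar sits next to it.
    format : {"delimited", "bids-physio"}
    fs : float, optional
        Sampling frequency when the file carries no time column.
    t0 : float
        Start time when the file/metadata carries none.

    Raises
    ------
    ValueError
        Non-uniform time column (max deviation of the sampling interval
        above 1% of the median interval), non-numeric rows, or fs <= 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bids-physio":
        return _read_bids_physio(path)
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")

    df = _read_delimited(path)
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric rows in {path}: {exc}") from None
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] >= 2:
        t, values = data[:, 0], data[:, 1]
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError("time column must be strictly increasing")
        if np.max(np.abs(dt - med)) > 0.01 * med:
            raise ValueError("non-uniform sampling: time column deviates >1% from a uniform grid")
        return RespirationTrace(values, fs=1.0 / med, t0=float(t[0]))
    if fs is None:
        raise ValueError("single-column input needs an explicit sampling frequency")
    return RespirationTrace(data[:, 0], fs=float(fs), t0=t0)


def _sidecar_for(path: Path) -> Path:
    stem = path.name
    for suffix in (".tsv.gz", ".tsv"):
        if stem.endswith(suffix):
            return path.with_name(stem[: -len(suffix)] + ".json")
    raise ValueError(f"cannot derive sidecar name for {path}")


def _read_bids_physio(path: Path) -> RespirationTrace:
    sidecar = _sidecar_for(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    fs = float(meta["SamplingFrequency"])
    t0 = float(meta.get("StartTime", 0.0))
    columns = meta.get("Columns")
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", header=None)
    if columns:
        df.columns = columns[: df.shape[1]]
        resp_cols = [c for c in df.columns if "resp" in str(c).lower()]
        col = resp_cols[0] if resp_cols else df.columns[0]
    else:
        col = df.columns[0]
    return RespirationTrace(df[col].to_numpy(dtype=float), fs=fs, t0=t0)


def read_events(path: str | Path) -> EventTable:
    """Read an event table with columns onset_s (or onset) and condition.

    Rows are sorted by onset; an empty file yields an empty table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = _read_delimited(path)
    except pd.errors.EmptyDataError:
        return EventTable(np.array([]), ())
    if df.empty:
        return EventTable(np.array([]), ())
    cols = {c.lower().strip(): c for c in df.columns}
    onset_col = cols.get("onset_s") or cols.get("onset")
    cond_col = cols.get("condition")
    if onset_col is None:
        raise ValueError("event table needs an onset_s (or onset) column")
    onsets = df[onset_col].to_numpy(dtype=float)
    if cond_col is None:
        conditions = ["event"] * len(onsets)
    else:
        conditions = [str(c) for c in df[cond_col]]
    return EventTable(onsets, tuple(conditions))


# ---------------------------------------------------------------------------
# writers


def write_trace(trace: RespirationTrace, path: str | Path) -> None:
    """Write a trace as two-column TSV (time_s, value), full precision."""
    t = trace.times
    with open(path, "w") as fh:
        fh.write("time_s\tvalue\n")
        for ti, vi in zip(t, trace.values):
            fh.write(f"{float(ti)!r}\t{float(vi)!r}\n")


def write_events(events: EventTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\tcondition\n")
        for t, c in zip(events.onsets, events.conditions):
            fh.write(f"{float(t)!r}\t{c}\n")


def write_results(result, path: str | Path) -> None:
    """Write a fitted result as a tidy delimited table.

    A GLM result produces one row per (condition, basis component) plus an
    intercept row; legacy scores produce one row per event with columns
    d_rp, rpq, d_rll.
    """
    # late imports to avoid circularity between io and modelling modules
    from .glm import GLMResult
    from .measures import LegacyScores

    if isinstance(result, GLMResult):
        rows = [
            {"condition": cond, "component": comp, "beta": b}
            for (cond, comp), b in zip(result.column_map, result.beta)
        ]
        pd.DataFrame(rows, columns=["condition", "component", "beta"]).to_csv(
            path, sep="\t", index=False
        )
    elif isinstance(result, LegacyScores):
        pd.DataFrame(
            {
                "onset_s": result.onsets,
                "condition": result.conditions,
                "d_rp": result.d_rp,
                "rpq": result.rpq,
                "d_rll": result.d_rll,
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")
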