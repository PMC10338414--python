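"""Heart-rate-variability features from RR-interval series, and fusion with
EEG feature vectors.

Time-domain parameters over 2-min / 30-s / 10-s segments:

* SDNN — sample standard deviation of the intervals (ms);
* RMSSD — root mean square of successive interval differences (ms);
* mean HR — 60000 / mean interval (bpm);
* SI — Baevsky stress index AMo / (2·Mo·MxDMn) from a 50-ms interval
  histogram (Mo modal-bin midpoint in s, AMo modal share in %, MxDMn range
  in s), a sympathetic-activity index;
* PNS / SNS — composite indices: mean z-score of (mean RR, RMSSD) and of
  (mean HR, SI) respectively, z-scored against the cohort under analysis.
  These are monotone analogues of the commercial indices of the same name,
  not numerically comparable to them.

Per the reliability restriction on ultra-short recordings, 10-s segments
populate RMSSD only; all other fields are NaN there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import CVResult, KNNParams, loocv
from .desnn import FeatureVector

__all__ = [
    "RRSeries",
    "HRVParams",
    "segment",
    "hrv_params",
    "cohort_hrv",
    "fuse",
    "fuse_dataset",
    "hrv_subset_search",
    "HRV_FIELDS",
]

HRV_FIELDS = ["PNS", "SNS", "SI", "SDNN", "RMSSD", "meanHR"]
SANE_BOUNDS_MS = (300.0, 2000.0)


@dataclass
class RRSeries:
    """RR (inter-beat) intervals in milliseconds, starting at time t0 (s)."""

    intervals: np.ndarray
    t0: float = 0.0
    subject: str | None = None
    label: str | int | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be 1-D")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def peak_times(self) -> np.ndarray:
        """R-peak times (s): t0, then cumulative intervals."""
        return self.t0 + np.concatenate([[0.0], np.cumsum(self.intervals) / 1000.0])

    def flag_outliers(self, bounds: tuple[float, float] = SANE_BOUNDS_MS) -> np.ndarray:
        return (self.intervals < bounds[0]) | (self.intervals > bounds[1])


@dataclass
class HRVParams:
    RMSSD: float
    SDNN: float
    meanHR: float
    SI: float
    PNS: float
    SNS: float
    segment_len: float

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in HRV_FIELDS} | {
            "segment_len": self.segment_len
        }


def segment(rr: RRSeries, start: float, length: float) -> RRSeries:
    """Intervals whose starting R-peak falls in [start, start+length).

    A boundary interval straddling the window edge belongs to the window that
    contains its starting R-peak.
    """
    starts = rr.peak_times[:-1]
    keep = (starts >= start) & (starts < start + length)
    if not keep.any():
        raise ValueError(f"no intervals in window [{start}, {start + length}) s")
    return RRSeries(rr.intervals[keep], t0=start, subject=rr.subject, label=rr.label)


def baevsky_si(intervals_ms: np.ndarray, bin_ms: float = 50.0) -> float:
    """Baevsky stress index from a fixed-width interval histogram.

    Bins are aligned to multiples of ``bin_ms``.  Degenerate series with zero
    range return +inf (vanishing variability → unbounded sympathetic index).
    """
    x = np.asarray(intervals_ms, dtype=np.float64)
    rng_ms = x.max() - x.min()
    if rng_ms == 0:
        return float("inf")
    lo = np.floor(x.min() / bin_ms) * bin_ms
    nbins = int(np.ceil((x.max() - lo) / bin_ms)) + 1
    edges = lo + bin_ms * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    k = int(np.argmax(counts))
    mo_s = (edges[k] + edges[k + 1]) / 2.0 / 1000.0
    amo_pct = 100.0 * counts[k] / x.size
    mxdmn_s = rng_ms / 1000.0
    return amo_pct / (2.0 * mo_s * mxdmn_s)


def hrv_params(rr: RRSeries, segment_len: float | None = None) -> HRVParams:
    """Time-domain HRV of one series.  PNS/SNS need a cohort (see
    :func:`cohort_hrv`) and are NaN here; 10-s segments emit RMSSD only."""
    x = rr.intervals
    if x.size < 3:
        raise ValueError(f"need >= 3 intervals, got {x.size}")
    if segment_len is None:
        segment_len = float(np.sum(x) / 1000.0)
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    if segment_len <= 10.0:
        nan = float("nan")
        return HRVParams(rmssd, nan, nan, nan, nan, nan, segment_len)
    sdnn = float(np.std(x, ddof=1))
    mean_hr = 60000.0 / float(np.mean(x))
    si = baevsky_si(x)
    nan = float("nan")
    return HRVParams(rmssd, sdnn, mean_hr, si, nan, nan, segment_len)


def cohort_hrv(series: Sequence[RRSeries], segment_len: float | None = None) -> pd.DataFrame:
    """Per-subject HRV table with PNS/SNS composites z-scored within the cohort."""
    rows = []
    for rr in series:
        p = hrv_params(rr, segment_len)
        rows.append(
            {"subject": rr.subject, "label": rr.label} | p.as_dict()
        )
    df = pd.DataFrame(rows)

    def z(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        return (col - col.mean()) / sd if sd > 0 else col * 0.0

    if df["SDNN"].notna().any():
        mean_rr = 60000.0 / df["meanHR"]
        fin_si = df["SI"].replace(np.inf, np.nan)
        fin_si = fin_si.fillna(fin_si.max() if fin_si.notna().any() else 0.0)
        df["PNS"] = (z(mean_rr) + z(df["RMSSD"])) / 2.0
        df["SNS"] = (z(df["meanHR"]) + z(fin_si)) / 2.0
    return df


def fuse(
    fv: FeatureVector,
    hrv: dict[str, float],
    stats: dict[str, tuple[float, float]] | None = None,
) -> FeatureVector:
    """Append HRV fields to a feature vector; an empty subset is the identity.

    ``stats`` maps field → (mean, sd) of the *training* cohort for
    z-normalization of the appended block; without it values pass through.
    """
    if not hrv:
        return fv
    clash = [k for k in hrv if k in fv.feature_names]
    if clash:
        raise ValueError(f"HRV names collide with existing features: {clash}")
    vals = []
    for k in sorted(hrv):
        v = float(hrv[k])
        if stats and k in stats:
            mu, sd = stats[k]
            v = (v - mu) / sd if sd > 0 else 0.0
        vals.append(v)
    return FeatureVector(
        np.concatenate([fv.values, vals]),
        fv.feature_names + sorted(hrv),
        fv.strategy,
        fv.label,
    )


def fuse_dataset(
    fvs: Sequence[FeatureVector], hrv_table: pd.DataFrame, fields: Sequence[str]
) -> list[FeatureVector]:
    """Fuse each subject's HRV fields (z-scored across the table) onto its
    feature vector; rows align by position."""
    if len(fvs) != len(hrv_table):
        raise ValueError("feature vectors and HRV table must align")
    if not fields:
        return list(fvs)
    stats = {
        f: (float(hrv_table[f].mean()), float(hrv_table[f].std(ddof=1)))
        for f in fields
    }
    out = []
    for fv, (_, row) in zip(fvs, hrv_table.iterrows()):
        out.append(fuse(fv, {f: row[f] for f in fields}, stats))
    return out


def hrv_subset_search(
    hrv_table: pd.DataFrame,
    labels: Sequence,
    params: KNNParams | None = None,
    fields: Sequence[str] | None = None,
) -> tuple[list[str], CVResult, pd.DataFrame]:
    """Exhaustively score every non-empty HRV parameter subset by LOOCV.

    Returns (best subset, its CV result, full table).  Ties prefer higher
    accuracy, then smaller subsets, then canonical field order.
    """
    params = params or KNNParams(k=3, feature_weighting="snr")
    if fields is None:
        fields = [f for f in HRV_FIELDS if f in hrv_table and hrv_table[f].notna().all()]
    if not fields:
        raise ValueError("no populated HRV parameters to search")
    y = np.asarray(labels)
    rows, results = [], []
    for r in range(1, len(fields) + 1):
        for combo in itertools.combinations(fields, r):
            X = hrv_table[list(combo)].to_numpy(dtype=np.float64)
            res = loocv(X, y, params)
            results.append((combo, res))
            rows.append({"subset": "+".join(combo), "size": r, "accuracy": res.accuracy})
    order = {f: i for i, f in enumerate(fields)}
    best_combo, best_res = max(
        results,
        key=lambda cr: (
            cr[1].accuracy,
            -len(cr[0]),
            tuple(-order[f] for f in cr[0]),
        ),
    )
    return list(best_combo), best_res, pd.DataFrame(rows)
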