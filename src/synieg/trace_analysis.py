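"""Nuclear reporter-trace extraction and summary statistics.

The summary statistics follow the conventions of live-cell reporter imaging:
the baseline of a trace is the mean of its first two timepoints, the AUC is
the plain (unweighted) sum of baseline-subtracted intensities over all
frames,

    AUC = sum_t ( intensity(t) - initial ),

fold-change is the final (or maximal) value over baseline, and kinetic
timing is read off the trace directly (argmax; first post-peak return to
within one noise SD of baseline).  Missing values are carried as NaN and
excluded from sums and means, never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .movie_synth import MovieStack

__all__ = [
    "IntensityTrace",
    "AUCResult",
    "ConditionSummary",
    "nuclear_mean_trace",
    "compute_auc",
    "fold_change",
    "kinetic_metrics",
    "aggregate",
]


@dataclass
class IntensityTrace:
    """A single-cell (or single-focus) intensity time series.

    ``values`` may contain NaN for frames where quantification failed.
    """

    times: np.ndarray
    values: np.ndarray
    label: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be matching 1-D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def baseline(self) -> float:
        """Mean of the first two timepoints (the trace's 'initial' value)."""
        if len(self.values) < 2:
            raise AnalysisError("baseline needs at least two timepoints")
        if np.isnan(self.values[:2]).any():
            raise AnalysisError("baseline undefined: first two timepoints missing")
        return float(self.values[:2].mean())


@dataclass(frozen=True)
class AUCResult:
    auc: float           # a.u. * frames
    baseline: float      # the 'initial' value subtracted from every frame
    n_timepoints: int    # frames entering the sum
    n_missing: int       # frames skipped as missing
    t_final: float


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n: int
    mean_auc: float
    sd_auc: float
    sem_auc: float
    mean_fold: float
    sd_fold: float
    sem_fold: float


def nuclear_mean_trace(movie: MovieStack, channel: str = "YFP",
                       mask: np.ndarray | None = None,
                       label: dict | None = None) -> IntensityTrace:
    """Mean masked intensity of the central z-slice of one channel, per frame.

    The central slice is the best-focus proxy; nuclear levels are quantified
    on acquired slices, not projections.
    """
    sub = movie.channel(channel)  # T x Z x Y x X
    if mask is None:
        if movie.ground_truth is None or movie.ground_truth[1] is None:
            raise ValidationError("no mask given and no geometry attached")
        mask = movie.ground_truth[1].nucleus_mask()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("nucleus mask is empty")
    z_mid = sub.shape[1] // 2
    values = sub[:, z_mid][:, mask].mean(axis=1)
    return IntensityTrace(times=movie.times_min, values=values,
                          label=dict(label or {}, channel=channel))


def compute_auc(trace: IntensityTrace) -> AUCResult:
    """Baseline-anchored AUC: plain sum of (value - initial) over all frames.

    The sum includes the first two (baseline) frames and skips missing
    values, reporting how many were skipped.  No dt weighting: units are
    a.u. * frames.
    """
    if len(trace.values) < 2:
        raise AnalysisError("AUC needs at least two timepoints")
    initial = trace.baseline
    dev = trace.values - initial
    missing = int(np.isnan(dev).sum())
    auc = float(np.nansum(dev))
    return AUCResult(
        auc=auc,
        baseline=initial,
        n_timepoints=len(dev) - missing,
        n_missing=missing,
        t_final=float(trace.times[-1]),
    )


def fold_change(trace: IntensityTrace, mode: str = "final") -> tuple[float, float]:
    """(fold, percent increase) of the endpoint — or maximum — over baseline.

    ``mode`` is "final" (default) or "max".
    """
    base = trace.baseline
    if base <= 0:
        raise AnalysisError(
            "baseline <= 0: fold-change undefined; add an offset or use AUC"
        )
    if mode == "final":
        if np.isnan(trace.values[-1]):
            raise AnalysisError("final timepoint is missing")
        ref = float(trace.values[-1])
    elif mode == "max":
        ref = float(np.nanmax(trace.values))
    else:
        raise ValidationError(f"unknown fold-change mode {mode!r}")
    fold = ref / base
    return fold, 100.0 * (fold - 1.0)


def kinetic_metrics(trace: IntensityTrace, noise_sd: float = 0.0,
                    t_stimulus: float = 0.0) -> dict[str, float | None]:
    """Timing metrics of a pulse-shaped trace, relative to stimulus time.

    ``time_to_peak_min`` is the argmax time; ``adaptation_time_min`` is the
    first post-peak time at which the trace has returned to within
    ``noise_sd`` of baseline (None if it never does).
    """
    vals = trace.values
    if np.isnan(vals).all():
        raise AnalysisError("trace is entirely missing")
    sel = trace.times >= t_stimulus
    if not sel.any():
        raise ValidationError("trace does not cover the stimulus epoch")
    t = trace.times[sel]
    v = vals[sel]
    base = trace.baseline
    i_peak = int(np.nanargmax(v))
    time_to_peak = float(t[i_peak] - t_stimulus)
    post = v[i_peak:]
    below = np.where(post <= base + noise_sd)[0]
    adaptation = float(t[i_peak + below[0]] - t_stimulus) if len(below) else None
    return {"time_to_peak_min": time_to_peak, "adaptation_time_min": adaptation}


def aggregate(traces_by_condition: dict[str, list[IntensityTrace]],
              fold_mode: str = "final") -> list[ConditionSummary]:
    """Per-condition mean/SD/SEM of per-trace AUC and fold-change.

    All traces within a condition must share one time grid.
    """
    out = []
    for cond, traces in traces_by_condition.items():
        if not traces:
            raise ValidationError(f"condition {cond!r} has no traces")
        t0 = traces[0].times
        for tr in traces[1:]:
            if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
                raise ValidationError(
                    f"mixed time grids within condition {cond!r}; resample first"
                )
        aucs = np.array([compute_auc(tr).auc for tr in traces])
        folds = np.array([fold_change(tr, fold_mode)[0] for tr in traces])
        n = len(traces)
        sd_a = float(aucs.std(ddof=1)) if n > 1 else 0.0
        sd_f = float(folds.std(ddof=1)) if n > 1 else 0.0
        out.append(ConditionSummary(
            condition=cond, n=n,
            mean_auc=float(aucs.mean()), sd_auc=sd_a, sem_auc=sd_a / np.sqrt(n),
            mean_fold=float(folds.mean()), sd_fold=sd_f, sem_fold=sd_f / np.sqrt(n),
        ))
    return out


# ---------------------------------------------------------------------------
# CSV schemas

def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(traces):
        cell = tr.label.get("cell_id", i)
        cond = tr.label.get("condition", "")
        for t, v in zip(tr.times, tr.values):
            rows.append((cell, cond, t, v))
    return pd.DataFrame(rows, columns=["cell_id", "condition", "time_min", "value"])


def traces_from_frame(df: pd.DataFrame) -> list[IntensityTrace]:
    required = {"cell_id", "condition", "time_min", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"trace table must have columns {sorted(required)}")
    df = df.copy()
    df["condition"] = df["condition"].fillna("")
    traces = []
    for (cell, cond), g in df.groupby(["cell_id", "condition"], sort=False):
        g = g.sort_values("time_min")
        traces.append(IntensityTrace(
            times=g["time_min"].to_numpy(),
            values=g["value"].to_numpy(),
            label={"cell_id": cell, "condition": cond},
        ))
    return traces


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "condition": s.condition, "n": s.n,
        "mean_auc": s.mean_auc, "sd_auc": s.sd_auc, "sem_auc": s.sem_auc,
        "mean_fold": s.mean_fold, "sd_fold": s.sd_fold, "sem_fold": s.sem_fold,
    } for s in summaries])
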