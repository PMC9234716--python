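"""Functional readouts for two-electrode voltage-clamp experiments.

Covers the analysis chain from raw current traces to summary statistics:

* peak extraction against a pre-application baseline (inward currents are
  stored negative; statistics downstream operate on magnitudes);
* per-recording Hill fits ``I = Imax * c^n / (c^n + EC50^n)`` in a
  log10-concentration parameterization, aggregated as mean ± SEM of EC50
  across recordings;
* day-batch normalization to a reference construct's maximal response;
* the paired sub-maximal/maximal potency ratio (e.g. I₃µM/I₃₀µM), a
  single-oocyte statistic that tracks agonist potency without a full
  concentration series;
* mutant classification against wild type by one-way-ANOVA-framed Dunnett
  comparison with Monte-Carlo critical values, preceded by a zero-response
  test;
* the paired conditioning-protocol fold-enhancement statistic used for
  peptide modulation of proton-gated currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ApplicationWindow",
    "CurrentTrace",
    "DoseResponseSet",
    "HillFit",
    "PotencyRatio",
    "MutantClass",
    "EnhancementResult",
    "measure_peak",
    "hill",
    "fit_hill",
    "fit_dose_response_set",
    "normalize_to_reference",
    "potency_ratio",
    "potency_ratio_from_traces",
    "classify_mutants",
    "dunnett_critical",
    "enhancement_ratio",
    "enhancement_from_traces",
    "ph_to_concentration",
    "concentration_to_ph",
]


@dataclass(frozen=True)
class ApplicationWindow:
    start: float  # s
    end: float  # s
    ligand: str = ""
    concentration: float = float("nan")  # M

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("window end must exceed start")


@dataclass
class CurrentTrace:
    """Sampled membrane current with ligand-application metadata.

    Inward currents are negative by convention; peak magnitudes are reported
    positive downstream.
    """

    time: np.ndarray  # s, monotone increasing
    current: np.ndarray  # µA
    application_windows: list[ApplicationWindow] = field(default_factory=list)
    holding_potential_mv: float = -60.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        t0, t1 = self.time[0], self.time[-1]
        for w in self.application_windows:
            if w.start < t0 or w.end > t1:
                raise ValueError(f"window {w} outside trace time range")


def measure_peak(
    trace: CurrentTrace, window: ApplicationWindow, baseline_s: float = 1.0
) -> float:
    """Baseline-subtracted peak current (µA) within an application window.

    Baseline is the median of the ``baseline_s`` seconds immediately before
    the window; the peak is the in-window extremum of (current − baseline),
    sign preserved. Requires a full baseline segment and at least 3 samples
    in the window.
    """
    if window.start - trace.time[0] < baseline_s:
        raise ValueError(
            f"need {baseline_s} s of pre-application baseline before t={window.start}"
        )
    pre = (trace.time >= window.start - baseline_s) & (trace.time < window.start)
    baseline = float(np.median(trace.current[pre]))
    inside = (trace.time >= window.start) & (trace.time <= window.end)
    if inside.sum() < 3:
        raise ValueError("application window covers fewer than 3 samples")
    delta = trace.current[inside] - baseline
    return float(delta[np.argmax(np.abs(delta))])


def baseline_sd(trace: CurrentTrace, window: ApplicationWindow, baseline_s: float = 1.0) -> float:
    """SD of the pre-application baseline segment; the noise-floor unit."""
    pre = (trace.time >= window.start - baseline_s) & (trace.time < window.start)
    return float(np.std(trace.current[pre]))


# ---------------------------------------------------------------------------
# Hill fitting


def hill(c: np.ndarray, ec50: float, n: float, imax: float) -> np.ndarray:
    """Hill dose-response: Imax * c^n / (c^n + EC50^n), evaluated stably in log space."""
    c = np.asarray(c, dtype=float)
    return imax / (1.0 + 10.0 ** (n * (np.log10(ec50) - np.log10(c))))


@dataclass(frozen=True)
class HillFit:
    ec50: float  # M
    hill_n: float
    imax: float  # µA (magnitude)
    rss: float
    converged: bool
    message: str = ""


def _init_from_halfmax(logc: np.ndarray, y: np.ndarray) -> float:
    """log10 EC50 guess: linear interpolation of the half-max crossing."""
    ymax = y.max()
    if ymax <= 0:
        return float(np.median(logc))
    half = ymax / 2.0
    order = np.argsort(logc)
    lc, yy = logc[order], y[order]
    above = yy >= half
    if above.all() or not above.any():
        return float(np.median(lc))
    i = int(np.argmax(above))  # first index at/above half-max
    if i == 0:
        return float(lc[0])
    x0, x1, y0, y1 = lc[i - 1], lc[i], yy[i - 1], yy[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_hill(
    concentrations: np.ndarray,
    peaks: np.ndarray,
    n_bounds: tuple[float, float] = (0.3, 10.0),
    init: tuple[float, float, float] | None = None,
) -> HillFit:
    """Least-squares Hill fit of one recording's (concentration, peak) pairs.

    Peaks may carry the inward-negative sign; magnitudes are fitted. EC50 is
    parameterized and bounded in log10 space ([min conc/100, max conc*100]),
    the Hill coefficient in ``n_bounds``. Non-convergence is reported via
    ``converged=False``, never silently.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.abs(np.asarray(peaks, dtype=float))
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations to fit")
    logc = np.log10(c)
    lo = np.array([logc.min() - 2.0, n_bounds[0], 1e-12])
    hi = np.array([logc.max() + 2.0, n_bounds[1], np.inf])
    if init is None:
        p0 = np.array([_init_from_halfmax(logc, y), 1.0, max(y.max(), 1e-9)])
    else:
        p0 = np.array([np.log10(init[0]), init[1], init[2]])
    p0 = np.clip(p0, lo, hi)

    def resid(p: np.ndarray) -> np.ndarray:
        log_ec50, n, imax = p
        return imax / (1.0 + 10.0 ** (n * (log_ec50 - logc))) - y

    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf")
    log_ec50, n, imax = sol.x
    return HillFit(
        ec50=float(10.0**log_ec50),
        hill_n=float(n),
        imax=float(imax),
        rss=float(2.0 * sol.cost),
        converged=bool(sol.success),
        message=str(sol.message),
    )


@dataclass
class DoseResponseSet:
    """Tidy peak-response table: one row per (recording, concentration).

    Columns: recording_id, batch_id, concentration_M, peak_uA, plus optional
    grouping columns (construct, ligand).
    """

    table: pd.DataFrame
    construct: str = ""
    ligand: str = ""

    REQUIRED = ("recording_id", "batch_id", "concentration_M", "peak_uA")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"dose-response table missing columns {missing}")
        if (self.table["concentration_M"] <= 0).any():
            raise ValueError("concentrations must be positive")
        if not np.isfinite(self.table["peak_uA"]).all():
            raise ValueError("non-finite peaks in table")


def fit_dose_response_set(ds: DoseResponseSet) -> dict:
    """Per-recording Hill fits with mean ± SEM aggregation of EC50.

    Also fits a single display curve to the per-concentration mean of
    recording-wise normalized (peak/Imax) responses, mirroring figure
    presentation; summary statistics come from the per-recording fits.
    """
    fits: dict[str, HillFit] = {}
    for rid, grp in ds.table.groupby("recording_id", sort=True):
        fits[str(rid)] = fit_hill(
            grp["concentration_M"].to_numpy(), grp["peak_uA"].to_numpy()
        )
    ec50s = np.array([f.ec50 for f in fits.values() if f.converged])
    ns = np.array([f.hill_n for f in fits.values() if f.converged])
    n_rec = len(ec50s)
    summary = {
        "n_recordings": n_rec,
        "n_nonconverged": sum(not f.converged for f in fits.values()),
        "ec50_mean": float(ec50s.mean()) if n_rec else float("nan"),
        "ec50_sem": float(ec50s.std(ddof=1) / np.sqrt(n_rec)) if n_rec > 1 else float("nan"),
        "ec50_median": float(np.median(ec50s)) if n_rec else float("nan"),
        "hill_n_mean": float(ns.mean()) if n_rec else float("nan"),
    }
    # display fit on mean normalized responses
    norm_rows = []
    for rid, fit in fits.items():
        if not fit.converged or fit.imax <= 0:
            continue
        grp = ds.table[ds.table["recording_id"].astype(str) == rid]
        norm_rows.append(
            pd.DataFrame(
                {
                    "concentration_M": grp["concentration_M"],
                    "norm": np.abs(grp["peak_uA"]) / fit.imax,
                }
            )
        )
    display_fit = None
    if norm_rows:
        mean_curve = (
            pd.concat(norm_rows).groupby("concentration_M")["norm"].mean().reset_index()
        )
        if len(mean_curve) >= 3:
            display_fit = fit_hill(
                mean_curve["concentration_M"].to_numpy(), mean_curve["norm"].to_numpy()
            )
    return {"per_recording": fits, "summary": summary, "display_fit": display_fit}


def normalize_to_reference(
    ds: DoseResponseSet,
    reference_construct: str,
    construct_col: str = "construct",
) -> pd.DataFrame:
    """Divide every peak by the same-batch mean maximal reference response.

    Each batch (recording day) must contain at least one reference
    recording; its mean response at the highest tested concentration
    defines 1.0 for that batch. Normalization is independent per batch so
    day-to-day expression differences cancel.
    """
    df = ds.table.copy()
    if construct_col not in df.columns:
        raise ValueError(f"table lacks a {construct_col!r} column")
    missing = []
    scales = {}
    for batch, grp in df.groupby("batch_id"):
        ref = grp[grp[construct_col] == reference_construct]
        if ref.empty:
            missing.append(batch)
            continue
        cmax = ref["concentration_M"].max()
        scales[batch] = np.abs(
            ref.loc[ref["concentration_M"] == cmax, "peak_uA"]
        ).mean()
    if missing:
        raise ValueError(
            f"batches lacking reference construct {reference_construct!r}: {missing}"
        )
    df["peak_norm"] = [
        abs(p) / scales[b] for p, b in zip(df["peak_uA"], df["batch_id"])
    ]
    return df


# ---------------------------------------------------------------------------
# Potency ratio and enhancement


@dataclass(frozen=True)
class PotencyRatio:
    ratio: float
    sem: float
    n: int
    conc_a: float
    conc_b: float
    per_recording: tuple[float, ...] = ()
    n_excluded: int = 0


def potency_ratio(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
    conc_a: float = 3e-6,
    conc_b: float = 30e-6,
    noise_floor: float = 0.0,
) -> PotencyRatio:
    """Per-oocyte |peak_a|/|peak_b| ratio, aggregated as mean ± SEM.

    ``peaks_a`` and ``peaks_b`` are paired (same recording). Recordings
    whose saturating response magnitude |peak_b| falls at or below
    ``noise_floor`` are excluded and counted rather than producing unstable
    ratios.
    """
    a = np.abs(np.asarray(peaks_a, dtype=float))
    b = np.abs(np.asarray(peaks_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("peaks_a and peaks_b must be paired (equal length)")
    keep = b > noise_floor
    ratios = a[keep] / b[keep]
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no recording exceeds the noise floor")
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return PotencyRatio(
        ratio=float(ratios.mean()),
        sem=sem,
        n=n,
        conc_a=conc_a,
        conc_b=conc_b,
        per_recording=tuple(float(r) for r in ratios),
        n_excluded=int((~keep).sum()),
    )


def _paired_window_peaks(
    traces: list[CurrentTrace], noise_floor_mult: float = 3.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[ApplicationWindow]]:
    """Extract (peaks_a, peaks_b, floors) from two-window paired recordings."""
    pa, pb, floors = [], [], []
    windows = []
    for tr in traces:
        if len(tr.application_windows) != 2:
            raise ValueError(
                f"paired protocol needs exactly 2 application windows, got "
                f"{len(tr.application_windows)}"
            )
        wa, wb = sorted(tr.application_windows, key=lambda w: w.start)
        pa.append(measure_peak(tr, wa))
        pb.append(measure_peak(tr, wb))
        floors.append(noise_floor_mult * baseline_sd(tr, wa))
        windows.append((wa, wb))
    return np.array(pa), np.array(pb), np.array(floors), windows


def potency_ratio_from_traces(
    traces: list[CurrentTrace], noise_floor_mult: float = 3.0
) -> PotencyRatio:
    """Peak extraction plus ratio statistic for two-application recordings.

    Each trace must carry exactly two application windows, the sub-maximal
    concentration first. The noise floor is ``noise_floor_mult`` times the
    pre-application baseline SD, per recording.
    """
    pa, pb, floors, windows = _paired_window_peaks(traces, noise_floor_mult)
    wa, wb = windows[0]
    keep = np.abs(pb) > floors
    if not keep.all():
        excluded = int((~keep).sum())
    else:
        excluded = 0
    res = potency_ratio(
        pa[keep], pb[keep], conc_a=wa.concentration, conc_b=wb.concentration
    )
    return PotencyRatio(
        ratio=res.ratio,
        sem=res.sem,
        n=res.n,
        conc_a=res.conc_a,
        conc_b=res.conc_b,
        per_recording=res.per_recording,
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class EnhancementResult:
    fold: float
    sem: float
    n: int
    per_recording: tuple[float, ...] = ()
    n_flagged: int = 0  # recordings whose control pulse sat below the floor


def enhancement_ratio(
    peaks_a: np.ndarray, peaks_b: np.ndarray, noise_floor: np.ndarray | float = 0.0
) -> EnhancementResult:
    """Per-recording fold = |peak_b| / |peak_a|, aggregated as mean ± SEM.

    ``peak_a`` is the test pulse after conditioning alone and ``peak_b``
    after conditioning plus peptide. Control pulses at or below the noise
    floor are not excluded (that would bias the fold upward-censored) but
    the fold is computed against the floor and the recording flagged.
    """
    a = np.abs(np.asarray(peaks_a, dtype=float))
    b = np.abs(np.asarray(peaks_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired peaks must have equal length")
    floor = np.broadcast_to(np.asarray(noise_floor, dtype=float), a.shape)
    flagged = a <= floor
    denom = np.where(flagged, np.maximum(floor, np.finfo(float).tiny), a)
    folds = b / denom
    n = len(folds)
    sem = float(folds.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return EnhancementResult(
        fold=float(folds.mean()),
        sem=sem,
        n=n,
        per_recording=tuple(float(f) for f in folds),
        n_flagged=int(flagged.sum()),
    )


def enhancement_from_traces(
    traces: list[CurrentTrace], noise_floor_mult: float = 3.0
) -> EnhancementResult:
    """Peak extraction plus fold-enhancement for paired conditioning recordings."""
    pa, pb, floors, _ = _paired_window_peaks(traces, noise_floor_mult)
    return enhancement_ratio(pa, pb, noise_floor=floors)


# ---------------------------------------------------------------------------
# Mutant classification (ANOVA frame + Monte-Carlo Dunnett)


@dataclass(frozen=True)
class MutantClass:
    label: str  # unchanged_or_greater | reduced | no_response
    p_vs_zero: float
    t_vs_wt: float
    dunnett_critical: float
    significant_vs_wt: bool


@lru_cache(maxsize=64)
def dunnett_critical(
    group_sizes: tuple[int, ...],
    df: int,
    alpha: float = 0.05,
    alternative: str = "less",
    n_draws: int = 50_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo critical value for the Dunnett many-to-one max statistic.

    ``group_sizes`` is (n_control, n_1, ..., n_k). Simulates the null
    distribution of the extreme standardized mean difference across the k
    comparisons, with the pooled-variance chi-square on ``df`` degrees of
    freedom shared across comparisons (the source of Dunnett's correlation
    structure, together with the shared control mean). Returns c such that
    under H0, P(min_i T_i < -c) = alpha ("less") or P(max_i |T_i| > c) = alpha
    ("two-sided").
    """
    if len(group_sizes) < 2:
        raise ValueError("need a control and at least one treatment group")
    rng = np.random.default_rng(seed)
    n0, ns = group_sizes[0], np.array(group_sizes[1:], dtype=float)
    z0 = rng.normal(0.0, np.sqrt(1.0 / n0), size=(n_draws, 1))
    zi = rng.normal(0.0, 1.0, size=(n_draws, len(ns))) / np.sqrt(ns)
    s = np.sqrt(rng.chisquare(df, size=(n_draws, 1)) / df)
    t = (zi - z0) / (s * np.sqrt(1.0 / ns + 1.0 / n0))
    if alternative == "less":
        m = (-t).max(axis=1)
    elif alternative == "two-sided":
        m = np.abs(t).max(axis=1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(np.quantile(m, 1.0 - alpha))


def classify_mutants(
    ratios: dict[str, np.ndarray],
    amplitudes: dict[str, np.ndarray] | None = None,
    wt: str = "WT",
    alpha: float = 0.05,
    alternative: str = "less",
    n_draws: int = 50_000,
    seed: int = 0,
) -> dict[str, MutantClass]:
    """Classify each construct's potency ratio against wild type.

    Two-stage rule per construct: (1) a one-sample two-sided t-test of raw
    response amplitudes against zero — constructs whose currents are
    indistinguishable from noise are labeled ``no_response`` before any
    ratio is interpreted; (2) the surviving constructs' ratios enter a
    one-way ANOVA frame (pooled variance) with Dunnett many-to-one
    comparison against WT: significantly less → ``reduced``, otherwise →
    ``unchanged_or_greater``. The default alternative is one-sided (lower)
    because only a potency *loss* is a distinct outcome class; constructs
    with greater ratios share the unchanged class.

    ``amplitudes`` maps construct → raw response amplitudes (µA; e.g. the
    pooled sub-maximal and maximal responses). If omitted, every construct
    is assumed responsive.
    """
    if wt not in ratios:
        raise ValueError(f"missing WT group {wt!r} in ratios")
    groups = {k: np.asarray(v, dtype=float) for k, v in ratios.items()}
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"construct {name!r} has fewer than 3 replicates")

    # stage 1: zero-response screen on raw amplitudes
    responsive = {}
    p_zero = {}
    for name in groups:
        if amplitudes is None or name not in amplitudes or name == wt:
            responsive[name] = True
            p_zero[name] = 0.0
            continue
        amp = np.asarray(amplitudes[name], dtype=float)
        t, p = stats.ttest_1samp(amp, 0.0)
        p_zero[name] = float(p)
        responsive[name] = p < alpha

    mutants = [k for k in groups if k != wt and responsive[k]]
    out: dict[str, MutantClass] = {}
    for name in groups:
        if name != wt and not responsive[name]:
            out[name] = MutantClass("no_response", p_zero[name], float("nan"), float("nan"), False)

    if mutants:
        # one-way ANOVA frame over WT + responsive mutants: pooled variance
        frame = [groups[wt]] + [groups[m] for m in mutants]
        sizes = tuple(len(g) for g in frame)
        df = sum(sizes) - len(sizes)
        pooled = np.sqrt(
            sum((len(g) - 1) * g.var(ddof=1) for g in frame) / df
        )
        crit = dunnett_critical(sizes, df, alpha, alternative, n_draws, seed)
        wt_mean, n0 = groups[wt].mean(), len(groups[wt])
        for m in mutants:
            g = groups[m]
            t = (g.mean() - wt_mean) / (pooled * np.sqrt(1.0 / len(g) + 1.0 / n0))
            if alternative == "less":
                sig = t < -crit
                lower = sig
            else:
                sig = abs(t) > crit
                lower = sig and g.mean() < wt_mean
            label = "reduced" if lower else "unchanged_or_greater"
            out[m] = MutantClass(label, p_zero[m], float(t), crit, bool(sig))

    out[wt] = MutantClass("unchanged_or_greater", 0.0, 0.0, float("nan"), False)
    return out


# ---------------------------------------------------------------------------
# pH adapter


def ph_to_concentration(ph: float) -> float:
    """Proton concentration (M) of a pH value, so Hill fitting covers pH series."""
    if not np.isfinite(ph):
        raise ValueError("pH must be finite")
    return float(10.0 ** (-ph))


def concentration_to_ph(c: float) -> float:
    if c <= 0:
        raise ValueError("concentration must be positive")
    return float(-np.log10(c))
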