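"""ERP waveform summaries and nonparametric group statistics.

Covers grand-average target ERPs, automated P300 peak measurement (maximum
positive value in a 250-600 ms window on a designated channel, Pz by
default), direction-wise 0.3-0.5 s mean amplitudes, and the statistical
machinery used to compare the VR and AR environments: Kolmogorov-Smirnov
normality screening, paired Wilcoxon signed-rank and two-sample rank-sum
tests (exact null distributions with midranks at small n, tie-corrected
normal approximation otherwise), Benjamini-Hochberg FDR adjustment, and
Pearson correlation. Alpha is 0.05 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet

__all__ = [
    "ErpWaveform",
    "PeakMeasure",
    "SubjectRecord",
    "StatResult",
    "ErpConfig",
    "average_target_erp",
    "find_p300_peak",
    "direction_mean_amplitude",
    "describe",
    "round2",
    "ks_normality",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "fdr_bh",
    "pearson_correlation",
    "preference_group_accuracy",
    "summarize_records",
    "compare_environments",
]

ALPHA = 0.05

#: Channels averaged under the "mean-parietal" channel policy.
PARIETAL_SET = ("Pz", "P3", "P4")


@dataclass(frozen=True)
class ErpConfig:
    """Peak-analysis settings: search window and measurement channel."""

    peak_window_ms: tuple[float, float] = (250.0, 600.0)
    mean_window_ms: tuple[float, float] = (300.0, 500.0)
    channel_policy: str = "Pz"


@dataclass
class ErpWaveform:
    """An averaged ERP: channels x samples, with provenance."""

    values: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    n_epochs_averaged: int
    environment: str = "NA"
    direction: int | str = "all"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.n_epochs_averaged <= 0:
            raise ValueError("n_epochs_averaged must be positive")
        if self.values.shape[0] != len(self.channel_labels):
            raise ValueError("row count must match channel labels")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.sampling_rate_hz * 1000.0

    def trace(self, channel_policy: str = "Pz") -> np.ndarray:
        """Single measurement trace per the channel policy (a channel label,
        or "mean-parietal" for the average of Pz/P3/P4)."""
        if channel_policy == "mean-parietal":
            idx = [self.channel_labels.index(ch) for ch in PARIETAL_SET
                   if ch in self.channel_labels]
            if not idx:
                raise ValueError("no parietal channels present")
            return self.values[idx].mean(axis=0)
        if channel_policy not in self.channel_labels:
            raise ValueError(f"channel {channel_policy!r} not in {self.channel_labels}")
        return self.values[self.channel_labels.index(channel_policy)]


@dataclass(frozen=True)
class PeakMeasure:
    latency_ms: float
    amplitude_uv: float
    search_window_ms: tuple[float, float]
    channel_policy: str

    def __post_init__(self) -> None:
        lo, hi = self.search_window_ms
        if not lo <= self.latency_ms <= hi:
            raise ValueError("latency outside its own search window")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's per-environment outcomes (accuracy %, P300 peak
    latency/amplitude, 3D-sickness flags, preferred environment)."""

    subject_id: str
    accuracy_vr: float
    accuracy_ar: float
    sickness_vr: bool
    sickness_ar: bool
    preference: str
    latency_vr: float
    latency_ar: float
    amplitude_vr: float
    amplitude_ar: float

    def __post_init__(self) -> None:
        for a in (self.accuracy_vr, self.accuracy_ar):
            if not 0 <= a <= 100:
                raise ValueError("accuracy must be a percentage in [0, 100]")
        if self.preference not in ("VR", "AR"):
            raise ValueError("preference must be 'VR' or 'AR'")


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    adjusted_p: float | None = None
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    @property
    def significant(self) -> bool:
        p = self.p_value if self.adjusted_p is None else self.adjusted_p
        return p < self.alpha


# ---------------------------------------------------------------------------
# Waveform summaries


def average_target_erp(
    epochs: EpochSet,
    *,
    environment: str | None = None,
    direction: int | None = None,
) -> ErpWaveform:
    """Pointwise mean of the (single-blink) target epochs, optionally
    restricted to one environment and/or one direction button."""
    mask = epochs.is_target.copy()
    if environment is not None:
        mask &= epochs.environment == environment
    if direction is not None:
        mask &= epochs.button == direction
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no target epochs in the requested group")
    return ErpWaveform(
        values=epochs.epochs[mask].mean(axis=0),
        sampling_rate_hz=epochs.sampling_rate_hz,
        channel_labels=epochs.channel_labels,
        n_epochs_averaged=n,
        environment=environment or "NA",
        direction="all" if direction is None else direction,
    )


def find_p300_peak(
    erp: ErpWaveform,
    window_ms: tuple[float, float] = (250.0, 600.0),
    channel_policy: str = "Pz",
) -> PeakMeasure:
    """Maximum positive value inside the window; ties take the earliest
    sample. Latency is the argmax sample time."""
    trace = erp.trace(channel_policy)
    times = erp.times_ms
    lo, hi = window_ms
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError("search window lies outside the epoch")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(trace[idx])]
    return PeakMeasure(
        latency_ms=float(times[best]),
        amplitude_uv=float(trace[best]),
        search_window_ms=(lo, hi),
        channel_policy=channel_policy,
    )


def direction_mean_amplitude(
    erp: ErpWaveform,
    window_ms: tuple[float, float] = (300.0, 500.0),
    channel_policy: str = "Pz",
) -> float:
    """Temporal mean of the trace over the window, boundary samples
    included (samples 30..50 at 100 Hz for 300-500 ms)."""
    trace = erp.trace(channel_policy)
    times = erp.times_ms
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError("window lies outside the epoch")
    return float(trace[mask].mean())


def describe(values) -> tuple[float, float]:
    """Mean and population standard deviation (divisor n)."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("describe() needs at least one value")
    return float(a.mean()), float(a.std(ddof=0))


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (reporting convention)."""
    return math.copysign(math.floor(abs(x) * 100 + 0.5) / 100, x)


# ---------------------------------------------------------------------------
# Statistical tests


def ks_normality(values) -> StatResult:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    own mean and (sample) SD; asymptotic p-value."""
    a = np.asarray(values, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 values")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = sstats.kstest(a, "norm", args=(a.mean(), sd), mode="asymp")
    return StatResult(statistic=float(stat), p_value=float(p), method="ks")


def _exact_tail_p(dist: np.ndarray, w2: int) -> float:
    """Two-sided p from a discrete null distribution over doubled statistics:
    2 * min(P(W <= w), P(W >= w)), capped at 1."""
    total = dist.sum()
    lower = dist[: w2 + 1].sum() / total
    upper = dist[w2:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y=None) -> StatResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; tied |differences| get midranks. For up to
    25 usable pairs the exact null distribution of W+ (sum of positive
    ranks) is built by dynamic programming over the doubled ranks, which
    stays exact under ties; beyond that a tie-corrected normal approximation
    with continuity correction is used. The reported statistic is W+.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate: all differences are zero")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1, dtype=float)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[:-r] if r else dist
            dist = dist + shifted
        p = _exact_tail_p(dist, int(round(2 * w_plus)))
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = 2 * sstats.norm.sf(abs(z))
    return StatResult(
        statistic=w_plus, p_value=min(1.0, float(p)), method="wilcoxon_signed_rank"
    )


def wilcoxon_rank_sum(group_a, group_b) -> StatResult:
    """Two-sample Wilcoxon rank-sum test, two-sided, midranks for ties.

    Exact null (all choose(n_a+n_b, n_a) assignments, via DP over doubled
    ranks) when the combined sample size is at most 20; tie-corrected normal
    approximation with continuity correction otherwise. The statistic is the
    rank sum of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sstats.rankdata(combined)
    w = float(ranks[:n1].sum())
    if n1 + n2 <= 20:
        r2 = np.rint(2 * ranks).astype(int)
        max_sum = int(r2.sum())
        # dp[k, s] = number of k-subsets of the ranks with doubled-sum s
        dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
        dp[0, 0] = 1.0
        for r in r2:
            new = dp.copy()
            new[1:, r:] += dp[:-1, : max_sum + 1 - r] if r else dp[:-1, :]
            dp = new
        dist = dp[n1]
        p = _exact_tail_p(dist, int(round(2 * w)))
    else:
        mean = n1 * (n1 + n2 + 1) / 2.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        n = n1 + n2
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
        p = 2 * sstats.norm.sf(abs(z))
    return StatResult(
        statistic=w, p_value=min(1.0, float(p)), method="wilcoxon_rank_sum"
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x, y) -> StatResult:
    """Sample Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate: zero variance")
    r, p = sstats.pearsonr(x, y)
    return StatResult(statistic=float(r), p_value=float(p), method="pearson")


# ---------------------------------------------------------------------------
# Group summaries over subject records


def _records_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def preference_group_accuracy(records: list[SubjectRecord]) -> dict:
    """Mean VR and AR accuracy within each preference group (2 dp)."""
    if any(r.preference not in ("VR", "AR") for r in records):
        raise ValueError("every record needs a preference")
    df = _records_frame(records)
    out: dict[str, dict] = {}
    for pref, grp in df.groupby("preference"):
        out[str(pref)] = {
            "n": int(len(grp)),
            "mean_accuracy_vr": round2(grp["accuracy_vr"].mean()),
            "mean_accuracy_ar": round2(grp["accuracy_ar"].mean()),
        }
    return out


def summarize_records(records: list[SubjectRecord]) -> dict:
    """Group means/SDs of accuracy, peak latency and amplitude (2 dp,
    population SD) plus the preference-group accuracy table."""
    df = _records_frame(records)
    out: dict = {"n_subjects": len(records)}
    for col in ("accuracy_vr", "accuracy_ar", "latency_vr", "latency_ar",
                "amplitude_vr", "amplitude_ar"):
        mean, sd = describe(df[col].to_numpy())
        out[f"mean_{col}"] = round2(mean)
        out[f"sd_{col}"] = round2(sd)
    out["mean_accuracy_overall"] = round2(
        np.concatenate([df["accuracy_vr"], df["accuracy_ar"]]).mean()
    )
    out["preference_groups"] = preference_group_accuracy(records)
    return out


def compare_environments(records: list[SubjectRecord]) -> dict:
    """Paired VR-vs-AR comparison of accuracy, peak latency and amplitude.

    Per field: KS normality screening of each environment's sample, a paired
    Wilcoxon signed-rank test, and the alpha = 0.05 verdict; BH-adjusted
    p-values are reported across the three paired tests. A field whose
    differences are all zero is reported as degenerate rather than tested.
    """
    df = _records_frame(records)
    fields = ("accuracy", "latency", "amplitude")
    report: dict = {"alpha": ALPHA, "fields": {}}
    raw_ps: dict[str, float] = {}
    for name in fields:
        vr = df[f"{name}_vr"].to_numpy()
        ar = df[f"{name}_ar"].to_numpy()
        entry: dict = {}
        for env, vals in (("vr", vr), ("ar", ar)):
            try:
                ks = ks_normality(vals)
                entry[f"ks_{env}"] = {"statistic": ks.statistic, "p": ks.p_value,
                                      "normal_at_alpha": not ks.significant}
            except ValueError as err:
                entry[f"ks_{env}"] = {"degenerate": str(err)}
        if np.all(vr == ar):
            entry["signed_rank"] = {"degenerate": "identical VR and AR values"}
        else:
            sr = wilcoxon_signed_rank(vr, ar)
            entry["signed_rank"] = {"statistic": sr.statistic, "p": sr.p_value}
            raw_ps[name] = sr.p_value
        report["fields"][name] = entry
    if raw_ps:
        adjusted = fdr_bh(list(raw_ps.values()))
        for name, adj in zip(raw_ps, adjusted):
            entry = report["fields"][name]["signed_rank"]
            entry["p_fdr"] = float(adj)
            entry["significant"] = bool(entry["p"] < ALPHA)
    return report
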