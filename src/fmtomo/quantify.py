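"""Downstream readouts: reconstruction summaries and longitudinal statistics.

Covers the quantities used to read out treatment response from a two-arm
imaging study: reconstructed source power / volume / centroid, caliper tumor
volume (0.5 * a * b^2 with a, b the longer and shorter diameters), percent
change between group means, per-day one-way ANOVA across groups at alpha =
0.05, and a longitudinal report flagging the first day of (persistent)
statistically significant divergence per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import SourceVolume, validate_study

__all__ = [
    "ReconSummary",
    "GroupComparison",
    "caliper_volume",
    "summarize_recon",
    "percent_change",
    "compare_groups",
    "longitudinal_report",
    "first_significant_day",
    "plot_study",
]

ALPHA = 0.05


@dataclass
class ReconSummary:
    """Summary of a reconstructed source volume.

    ``total_power`` integrates the (clamped) yield density over the volume;
    ``volume_mm3`` counts voxels above ``threshold_frac`` of the maximum;
    ``localization_error_mm`` is present only when a truth volume is given.
    """

    total_power: float
    volume_mm3: float
    centroid_mm: tuple[float, float, float] | None
    localization_error_mm: float | None = None
    threshold_frac: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupComparison:
    """One-way ANOVA comparison of two (or more) groups at one time point."""

    day: int
    metric: str
    group_means: dict
    group_sds: dict
    n_per_group: dict
    F: float
    p: float

    @property
    def significant(self) -> bool:
        return bool(self.p < ALPHA)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def caliper_volume(a: float, b: float) -> float:
    """Caliper tumor volume 0.5 * a * b^2 (mm^3).

    ``a`` and ``b`` are the longer and shorter tumor diameters in mm.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("diameters must be positive")
    if np.any(b > a):
        raise ValueError("shorter diameter b exceeds a: diameters swapped?")
    result = 0.5 * a * b ** 2
    return float(result) if result.ndim == 0 else result


def percent_change(reference: float, value: float) -> float:
    """Percent decrease of ``value`` relative to ``reference``.

    Positive when ``value`` is below ``reference`` (e.g. a treated-group mean
    below the control mean).
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference


def summarize_recon(
    recon: SourceVolume,
    threshold_frac: float = 0.5,
    truth: SourceVolume | None = None,
) -> ReconSummary:
    """Summarize a reconstructed SourceVolume.

    Negative yields (possible for unclamped signed solutions) are clamped to
    zero before integration. The volume readout counts voxels whose yield
    exceeds ``threshold_frac`` times the maximum (half-maximum by default).
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    y = np.maximum(recon.yield_, 0.0)
    vv = recon.voxel_size ** 3
    total_power = float(y.sum() * vv)
    if total_power == 0.0:
        return ReconSummary(
            total_power=0.0,
            volume_mm3=0.0,
            centroid_mm=None,
            localization_error_mm=None,
            threshold_frac=threshold_frac,
        )
    threshold = threshold_frac * y.max()
    volume_mm3 = float((y > threshold).sum() * vv)
    idx = np.indices(y.shape).reshape(3, -1)
    w = y.ravel()
    centroid = ((idx * w).sum(axis=1) / w.sum() + 0.5) * recon.voxel_size
    loc_err = None
    if truth is not None and truth.truth_centroid is not None:
        loc_err = float(np.linalg.norm(centroid - truth.truth_centroid))
    return ReconSummary(
        total_power=total_power,
        volume_mm3=volume_mm3,
        centroid_mm=tuple(float(v) for v in centroid),
        localization_error_mm=loc_err,
        threshold_frac=threshold_frac,
    )


def _metric_values(df: pd.DataFrame, metric: str) -> pd.Series:
    if metric == "intensity":
        return df["intensity"]
    if metric in ("caliper_volume", "volume"):
        return 0.5 * df["a_mm"] * df["b_mm"] ** 2
    if metric in ("weight", "body_weight"):
        return df["weight_g"]
    if metric in df.columns:
        return df[metric]
    raise ValueError(f"unknown metric {metric!r}")


def compare_groups(study: pd.DataFrame, metric: str = "intensity", day: int = 0) -> GroupComparison:
    """One-way ANOVA of ``metric`` across groups at one measurement day.

    Degenerate inputs are handled explicitly: equal group means with zero
    within-group variance give F = 0, p = 1; differing means with zero
    within-group variance give F = inf, p = 0.
    """
    sub = study[study["day"] == day]
    if sub.empty:
        raise ValueError(f"no records at day {day}")
    groups = sorted(sub["group"].unique())
    samples = [
        _metric_values(sub[sub["group"] == g], metric).to_numpy(dtype=float)
        for g in groups
    ]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 animals per group for ANOVA")
    means = {g: float(np.mean(s)) for g, s in zip(groups, samples)}
    sds = {g: float(np.std(s, ddof=1)) for g, s in zip(groups, samples)}
    ns = {g: int(len(s)) for g, s in zip(groups, samples)}

    within_var = sum(np.var(s, ddof=1) for s in samples)
    mean_vals = np.array(list(means.values()))
    if within_var == 0.0:
        if np.allclose(mean_vals, mean_vals[0]):
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F, p = stats.f_oneway(*samples)
        F, p = float(F), float(p)
        if np.isnan(F):  # constant data: scipy returns nan
            F, p = 0.0, 1.0
    return GroupComparison(
        day=int(day), metric=metric, group_means=means, group_sds=sds,
        n_per_group=ns, F=F, p=p,
    )


def first_significant_day(
    comparisons: list[GroupComparison], persistent: bool = True
) -> int | None:
    """Earliest day of significant group divergence.

    With ``persistent`` (default), the flagged day and all later measured
    days must be significant — sustained divergence; otherwise the first
    significant day alone qualifies. Returns None when no day qualifies.
    """
    comps = sorted(comparisons, key=lambda c: c.day)
    flags = [c.significant for c in comps]
    for i, c in enumerate(comps):
        if persistent:
            if all(flags[i:]):
                return c.day
        elif flags[i]:
            return c.day
    return None


def longitudinal_report(
    study: pd.DataFrame,
    metrics: tuple[str, ...] = ("intensity", "caliper_volume", "body_weight"),
    persistent: bool = True,
    expected_days: tuple[int, ...] | None = None,
) -> dict:
    """Per-day group comparisons, growth-rate fits, and divergence flags.

    Returns a dict with, per metric, the list of per-day
    :class:`GroupComparison` results and the first (persistently)
    significant day; plus per-animal log-linear intensity growth-rate fits
    and per-group mean rates; and an explicit list of expected-but-missing
    days (no silent interpolation).
    """
    validate_study(study)
    days = sorted(study["day"].unique())
    missing_days = []
    if expected_days is not None:
        missing_days = sorted(set(expected_days) - set(days))

    by_metric: dict[str, dict] = {}
    for metric in metrics:
        comps = [compare_groups(study, metric=metric, day=d) for d in days]
        by_metric[metric] = {
            "comparisons": comps,
            "first_significant_day": first_significant_day(comps, persistent),
        }

    # per-animal log-linear growth rates of intensity vs day
    rates = []
    for aid, sub in study.groupby("animal_id"):
        sub = sub.sort_values("day")
        slope = np.polyfit(sub["day"].to_numpy(float), np.log(sub["intensity"].to_numpy(float)), 1)[0]
        rates.append({"animal_id": aid, "group": sub["group"].iloc[0], "growth_rate": float(slope)})
    rates_df = pd.DataFrame(rates)
    group_rates = rates_df.groupby("group")["growth_rate"].mean().to_dict()

    return {
        "days": [int(d) for d in days],
        "missing_days": [int(d) for d in missing_days],
        "metrics": by_metric,
        "growth_rates": rates_df,
        "group_mean_growth_rates": {k: float(v) for k, v in group_rates.items()},
    }


def plot_study(study: pd.DataFrame, path, metric: str = "intensity"):
    """Plot per-day group means +- SD of a study metric to a file (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    validate_study(study)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, style in (("control", "o-"), ("treated", "s--")):
        sub = study[study["group"] == group]
        vals = sub.assign(v=_metric_values(sub, metric)).groupby("day")["v"]
        ax.errorbar(vals.mean().index, vals.mean(), yerr=vals.std(ddof=1),
                    fmt=style, capsize=3, label=group)
    ax.set_xlabel("day post-treatment")
    ax.set_ylabel(metric)
    if metric == "intensity":
        ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
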