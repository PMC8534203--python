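"""Group summaries and between-condition inference for crossover data.

The discrimination logic of the DEP signature study is group-level: per
condition, the per-cell crossover frequencies are summarized as in a
violin plot (n, median, SD, quartiles, extremes), and conditions are
compared by classical one-way fixed-effects ANOVA with the usual star
convention (* p<0.05, ** p<0.01, *** p<0.001).  The headline result this
reproduces is that the UHF crossover fx02 separates stem-like from
differentiated populations at *** while the low-frequency fx01 does not.

A rank-based alternative (Kruskal–Wallis) is available behind a flag for
robustness checks on skewed data; the operative inference is ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .measurement_protocol import MeasurementRecord

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "anova_oneway",
    "compare_conditions",
    "report_to_markdown",
    "violin_figure",
]

#: Star thresholds, strictest first.
_STARS = (("***", 1e-3), ("**", 1e-2), ("*", 5e-2))

#: Report footer: the operative convention is the star thresholds; a
#: stricter p < 0.005 significance convention is sometimes used alongside
#: them and is noted here rather than enforced.
REPORT_FOOTER = (
    "Significance stars: * p<0.05, ** p<0.01, *** p<0.001 (operative "
    "convention). A stricter p<0.005 significance threshold is noted as an "
    "alternative convention but is not enforced in these verdicts."
)


def significance_stars(p_value: float) -> str:
    for stars, thr in _STARS:
        if p_value < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    """Violin-plot statistics of one condition's crossover values (Hz)."""

    label: str
    n: int
    median: float
    sd: float
    q1: float
    q3: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class ComparisonResult:
    """One-way ANOVA outcome for a set of groups."""

    groups: tuple[str, ...]
    f_statistic: float
    p_value: float
    significance_stars: str
    degenerate: bool = False  # zero within-group variance with unequal means


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Descriptive summary: median (midpoint convention), SD (n−1),
    quartiles by linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return GroupSummary(
        label=label, n=int(v.size), median=float(np.median(v)), sd=sd,
        q1=float(q1), q3=float(q3),
        minimum=float(v.min()), maximum=float(v.max()),
    )


def anova_oneway(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    method: str = "anova",
) -> ComparisonResult:
    """Classical one-way fixed-effects ANOVA across ``groups``.

    F = MS_between/MS_within with (k−1, N−k) degrees of freedom.  Each
    group needs n ≥ 2.  Zero within-group variance with unequal means is
    reported as F = inf, p = 0 with the ``degenerate`` flag set.  With
    ``method="rank"`` a Kruskal–Wallis test is run instead (H statistic
    in place of F).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    names = tuple(labels) if labels is not None else tuple(
        f"group{i}" for i in range(len(arrays))
    )

    if method == "rank":
        h, p = sps.kruskal(*arrays)
        return ComparisonResult(names, float(h), float(p), significance_stars(p))
    if method != "anova":
        raise ValueError("method must be 'anova' or 'rank'")

    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return ComparisonResult(names, 0.0, 1.0, "ns")
        return ComparisonResult(names, float("inf"), 0.0, "***", degenerate=True)
    if ssb == 0.0:
        return ComparisonResult(names, 0.0, 1.0, "ns")
    f, p = sps.f_oneway(*arrays)
    return ComparisonResult(names, float(f), float(p), significance_stars(float(p)))


def _records_by_condition(records: Iterable[MeasurementRecord]):
    by: dict[str, dict[str, list[float]]] = {}
    for r in records:
        d = by.setdefault(r.condition, {"fx01": [], "fx02": []})
        d["fx01"].append(r.measured_fx01)
        d["fx02"].append(r.measured_fx02)
    return by


def compare_conditions(
    records: Iterable[MeasurementRecord],
    comparisons: Sequence[Sequence[str]] | None = None,
    method: str = "anova",
) -> dict:
    """Full group-comparison report over measured crossover records.

    Emits, per frequency (fx01, fx02): per-condition summaries, the
    omnibus ANOVA across all conditions, the requested pairwise/grouped
    ANOVAs, and a discriminability verdict (the star string of the
    omnibus test).  ``comparisons`` is a list of label groups, each with
    at least two distinct labels present in ``records``.
    """
    by = _records_by_condition(records)
    if not by:
        raise ValueError("no records supplied")
    labels = list(by)
    if comparisons is None:
        comparisons = [labels] if len(labels) >= 2 else []
    for comp in comparisons:
        if len(set(comp)) < 2:
            raise ValueError(f"comparison {list(comp)!r} needs at least two distinct conditions")
        for lab in comp:
            if lab not in by:
                raise ValueError(f"unknown condition label {lab!r}")

    report: dict = {"conditions": labels, "frequencies": {}, "footer": REPORT_FOOTER}
    for key in ("fx01", "fx02"):
        summaries = {lab: asdict(summarize(by[lab][key], lab)) for lab in labels}
        entry: dict = {"summaries": summaries, "comparisons": []}
        if len(labels) >= 2:
            omni = anova_oneway([by[lab][key] for lab in labels], labels, method=method)
            entry["omnibus"] = asdict(omni)
            entry["verdict"] = {
                "significant": omni.significance_stars != "ns",
                "stars": omni.significance_stars,
            }
        for comp in comparisons:
            res = anova_oneway([by[lab][key] for lab in comp], list(comp), method=method)
            entry["comparisons"].append(asdict(res))
        report["frequencies"][key] = entry
    return report


def report_to_markdown(report: Mapping) -> str:
    """Render a comparison report as Markdown tables."""
    lines: list[str] = []
    for key, entry in report["frequencies"].items():
        unit, scale = ("kHz", 1e3) if key == "fx01" else ("MHz", 1e6)
        lines.append(f"## {key}\n")
        lines.append(f"| condition | n | median ({unit}) | SD ({unit}) | Q1 | Q3 | min | max |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for lab, s in entry["summaries"].items():
            lines.append(
                "| {} | {} | {:.1f} | {:.1f} | {:.1f} | {:.1f} | {:.1f} | {:.1f} |".format(
                    lab, s["n"], s["median"] / scale, s["sd"] / scale,
                    s["q1"] / scale, s["q3"] / scale,
                    s["minimum"] / scale, s["maximum"] / scale,
                )
            )
        lines.append("")
        if entry["comparisons"] or "omnibus" in entry:
            lines.append("| comparison | F | p | stars |")
            lines.append("|---|---|---|---|")
            rows = ([entry["omnibus"]] if "omnibus" in entry else []) + list(entry["comparisons"])
            for c in rows:
                lines.append(
                    "| {} | {:.3g} | {:.3g} | {} |".format(
                        " vs ".join(c["groups"]), c["f_statistic"], c["p_value"],
                        c["significance_stars"],
                    )
                )
            lines.append("")
    lines.append(report.get("footer", ""))
    return "\n".join(lines)


def violin_figure(records, path, frequency: str = "fx02"):
    """Violin plot of per-condition crossover distributions (figure only;
    kernel-density curves are never used in computed results)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by = _records_by_condition(records)
    unit, scale = ("kHz", 1e3) if frequency == "fx01" else ("MHz", 1e6)
    labels = list(by)
    data = [np.asarray(by[lab][frequency]) / scale for lab in labels]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(labels), 4))
    parts = ax.violinplot(data, showmedians=True, showextrema=True)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel(f"{frequency} ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
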