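"""Clinical validation statistics: IHC scoring, dichotomization, association, survival.

Immunohistochemical staining of a marker in a tumor section is summarised by
an immunoreactive score (IRS): the product of a percentage-of-positive-cells
category (0: 0%, 1: 1-10%, 2: 11-50%, 3: >50%) and a staining-intensity score
(0 negative .. 3 strong), giving an integer in 0..9.  A cohort is split into
"high" and "low" expressors at the marker's median IRS (strictly above the
median is high).  Validation of a marker pair then covers:

* association of expression labels with clinicopathological covariates
  (Pearson chi-square on the contingency table);
* correlation between the two markers' IRS (Spearman);
* survival differences (Kaplan-Meier curves, log-rank test) for overall and
  disease-free survival, per marker, for the combined high/high group versus
  the rest, and across the four combined expression groups.

Chi-square, Spearman, Kaplan-Meier and log-rank computations are delegated to
scipy / lifelines; this module owns the scoring, splitting and report
assembly logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

COMBINED_GROUPS = ("high/high", "high/low", "low/high", "low/low")


class ClinicalInputError(ValueError):
    """Out-of-range scores, degenerate tables, mismatched patient ids."""


# ---------------------------------------------------------------------------
# IHC scoring
# ---------------------------------------------------------------------------


def pct_category(pct: float) -> int:
    """Percentage-of-positive-cells category: 0 (0%), 1 (1-10%], 2 (10-50%], 3 (>50%)."""
    if not 0 <= pct <= 100:
        raise ClinicalInputError(f"percentage must be in [0, 100], got {pct}")
    if pct == 0:
        return 0
    if pct <= 10:
        return 1
    if pct <= 50:
        return 2
    return 3


def irs(pct_cat: int, intensity: int) -> int:
    """Immunoreactive score: percentage category times intensity, range 0-9."""
    if pct_cat not in (0, 1, 2, 3):
        raise ClinicalInputError(f"percentage category must be 0-3, got {pct_cat}")
    if intensity not in (0, 1, 2, 3):
        raise ClinicalInputError(f"intensity must be 0-3, got {intensity}")
    return pct_cat * intensity


@dataclass(frozen=True)
class IHCScore:
    """One marker's staining read-out for one patient."""

    pct_positive: float
    pct_category: int
    intensity: int
    irs: int

    @classmethod
    def from_raw(cls, pct_positive: float, intensity: int) -> "IHCScore":
        cat = pct_category(pct_positive)
        return cls(pct_positive, cat, intensity, irs(cat, intensity))


@dataclass
class CohortRecord:
    """One patient: IHC scores per marker, covariates, survival outcomes.

    ``labels`` is empty until :func:`dichotomize` has been applied.
    ``true_group`` carries the simulated ground-truth expression group when
    the record came from the synthetic generator; it is ``None`` for real
    data and is never consulted by the validation statistics.
    """

    patient_id: str
    scores: dict[str, IHCScore]
    covariates: dict[str, str]
    time_os: float
    event_os: bool
    time_dfs: float
    event_dfs: bool
    labels: dict[str, str] = field(default_factory=dict)
    true_group: str | None = None


def dichotomize(scores: Sequence[float]) -> list[str]:
    """Median split: strictly above the median -> "high", otherwise "low"."""
    if len(scores) == 0:
        raise ClinicalInputError("dichotomize: empty score list")
    med = float(np.median(np.asarray(scores, dtype=float)))
    return ["high" if s > med else "low" for s in scores]


def label_cohort(records: Sequence[CohortRecord], marker: str) -> None:
    """Dichotomize one marker's IRS across the cohort, writing per-record labels."""
    labels = dichotomize([r.scores[marker].irs for r in records])
    for r, lab in zip(records, labels):
        r.labels[marker] = lab


def combined_group(rec: CohortRecord, marker_a: str, marker_b: str) -> str:
    """Four-way combined expression group, e.g. ``"high/low"`` for A-high/B-low."""
    return f"{rec.labels[marker_a]}/{rec.labels[marker_b]}"


def group_composition(groups: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages of each group label (percentages of the total n)."""
    n = len(groups)
    counts = pd.Series(groups).value_counts()
    return pd.DataFrame(
        {"count": counts, "percent": (100.0 * counts / n).round(2)}
    )


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------


def crosstab(
    labels: Mapping[str, str], covariate: Mapping[str, str]
) -> pd.DataFrame:
    """2-way count table over patients present in both maps."""
    shared = sorted(set(labels) & set(covariate))
    if not shared:
        raise ClinicalInputError("crosstab: no shared patient ids")
    return pd.crosstab(
        pd.Series([labels[p] for p in shared], name="label"),
        pd.Series([covariate[p] for p in shared], name="covariate"),
    )


def chi_square_test(
    table: pd.DataFrame | np.ndarray, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, degrees of freedom, p).  Yates continuity correction
    is off by default and only meaningful for 2x2 tables.
    """
    arr = np.asarray(table, dtype=float)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        raise ClinicalInputError(
            f"chi_square_test: zero row margin at row {int(np.argmin(row_sums))}"
        )
    if (col_sums == 0).any():
        raise ClinicalInputError(
            f"chi_square_test: zero column margin at column {int(np.argmin(col_sums))}"
        )
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ClinicalInputError("spearman_rho: need two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ClinicalInputError("spearman_rho: constant vector, correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def km_estimate(
    times: Sequence[float], events: Sequence[bool]
) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a frame with columns ``time``, ``survival``, ``at_risk`` (one row
    per observed time, survival evaluated just after that time).  S(0) = 1 and
    the curve is non-increasing; with no events it stays at 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ClinicalInputError("km_estimate: negative survival time")
    if len(t) == 0 or len(t) != len(e):
        raise ClinicalInputError("km_estimate: need equal-length non-empty vectors")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]],
) -> tuple[float, int, float]:
    """Log-rank comparison of >= 2 survival curves.

    Observed-minus-expected event counts with hypergeometric variance;
    statistic is chi-square distributed with (groups - 1) df under the null.
    """
    if len(groups) < 2:
        raise ClinicalInputError("logrank_test: need at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        if len(t) == 0:
            raise ClinicalInputError(f"logrank_test: group {i} is empty")
        times.extend(float(x) for x in t)
        events.extend(bool(x) for x in e)
        labels.extend([i] * len(t))
    res = multivariate_logrank_test(times, labels, events)
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


# ---------------------------------------------------------------------------
# cohort I/O and the full validation report
# ---------------------------------------------------------------------------

_OUTCOME_COLS = ("time_os", "event_os", "time_dfs", "event_dfs")


def write_cohort(
    records: Sequence[CohortRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a cohort table: one row per patient, two columns per marker."""
    markers = sorted(records[0].scores) if records else []
    covs = sorted(records[0].covariates) if records else []
    rows = []
    for r in records:
        row: dict[str, object] = {"patient_id": r.patient_id}
        for m in markers:
            row[f"{m}_pct"] = r.scores[m].pct_positive
            row[f"{m}_intensity"] = r.scores[m].intensity
        for c in covs:
            row[c] = r.covariates[c]
        row.update(
            time_os=r.time_os,
            event_os=int(r.event_os),
            time_dfs=r.time_dfs,
            event_dfs=int(r.event_dfs),
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_cohort(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[CohortRecord]:
    """Read a delimited cohort table.

    Markers are inferred from paired ``<name>_pct`` / ``<name>_intensity``
    columns; ``column_map`` renames non-standard input columns to the
    expected ones (e.g. ``{"os_months": "time_os"}``) before parsing.
    Remaining columns are treated as categorical covariates.
    """
    path = Path(path)
    sep = delimiter
    if sep is None:
        with path.open() as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in ("patient_id", *_OUTCOME_COLS) if c not in df.columns]
    if missing:
        raise ClinicalInputError(f"{path}: missing column(s) {missing}")
    markers = sorted(
        c[:-4]
        for c in df.columns
        if c.endswith("_pct") and f"{c[:-4]}_intensity" in df.columns
    )
    cov_cols = [
        c
        for c in df.columns
        if c != "patient_id"
        and c not in _OUTCOME_COLS
        and not any(c.startswith(m) for m in markers)
    ]
    records = []
    for _, row in df.iterrows():
        scores = {
            m: IHCScore.from_raw(float(row[f"{m}_pct"]), int(row[f"{m}_intensity"]))
            for m in markers
        }
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                scores=scores,
                covariates={c: str(row[c]) for c in cov_cols},
                time_os=float(row["time_os"]),
                event_os=bool(int(row["event_os"])),
                time_dfs=float(row["time_dfs"]),
                event_dfs=bool(int(row["event_dfs"])),
            )
        )
    return records


def _survival_block(
    records: Sequence[CohortRecord], group_of: Mapping[str, str], which: str
) -> dict:
    """KM + log-rank for one endpoint ('os' or 'dfs') over given patient groups."""
    by_group: dict[str, tuple[list[float], list[bool]]] = {}
    for r in records:
        g = group_of[r.patient_id]
        t = r.time_os if which == "os" else r.time_dfs
        e = r.event_os if which == "os" else r.event_dfs
        by_group.setdefault(g, ([], []))[0].append(t)
        by_group[g][1].append(e)
    names = sorted(by_group)
    if len(names) < 2:
        # degenerate labelling (e.g. the cohort median IRS equals the top
        # score, so no patient is strictly above it): nothing to compare
        return {
            "groups": names,
            "n": {g: len(by_group[g][0]) for g in names},
            "error": "fewer than two groups, survival comparison undefined",
        }
    stat, df, p = logrank_test([by_group[g] for g in names])
    return {
        "groups": names,
        "n": {g: len(by_group[g][0]) for g in names},
        "events": {g: int(sum(by_group[g][1])) for g in names},
        "logrank_statistic": stat,
        "df": df,
        "p": p,
        "significant": bool(p < 0.05),
        "km": {
            g: km_estimate(*by_group[g]).to_dict(orient="list") for g in names
        },
    }


def validate_markers(
    records: Sequence[CohortRecord],
    markers: tuple[str, str],
    covariates: Sequence[str] | None = None,
    extra_markers: Sequence[str] = (),
) -> dict:
    """Full clinical validation of a marker pair on one cohort.

    Dichotomizes each marker at its cohort median IRS, forms the four combined
    expression groups, tests association of each labelling with each covariate
    (chi-square), computes the Spearman correlation between the two markers'
    IRS, and compares overall and disease-free survival by marker, by
    high/high-versus-rest, and across the four combined groups.

    Any ``extra_markers`` (e.g. a downstream pathway read-out) are compared
    across the four combined groups both as a dichotomized label (chi-square)
    and on the raw IRS scale (Kruskal-Wallis), since either convention is
    defensible; both results are labelled in the report.
    """
    if len(records) == 0:
        raise ClinicalInputError("validate_markers: empty cohort")
    ma, mb = markers
    for m in (ma, mb, *extra_markers):
        label_cohort(records, m)
    covariates = list(
        covariates if covariates is not None else sorted(records[0].covariates)
    )

    groups = {r.patient_id: combined_group(r, ma, mb) for r in records}
    comp = group_composition(list(groups.values()))

    report: dict = {
        "n_patients": len(records),
        "markers": [ma, mb],
        "median_irs": {
            m: float(np.median([r.scores[m].irs for r in records]))
            for m in (ma, mb)
        },
        "group_composition": {
            g: {"count": int(comp.loc[g, "count"]), "percent": float(comp.loc[g, "percent"])}
            for g in comp.index
        },
        "spearman_rho": spearman_rho(
            [r.scores[ma].irs for r in records],
            [r.scores[mb].irs for r in records],
        ),
    }

    # association with clinicopathological covariates
    assoc: dict = {}
    labellings = {
        ma: {r.patient_id: r.labels[ma] for r in records},
        mb: {r.patient_id: r.labels[mb] for r in records},
        f"{ma}/{mb}": {
            p: ("high/high" if g == "high/high" else "other")
            for p, g in groups.items()
        },
    }
    for cov in covariates:
        cov_map = {r.patient_id: r.covariates[cov] for r in records}
        assoc[cov] = {}
        for name, lab in labellings.items():
            table = crosstab(lab, cov_map)
            try:
                stat, df, p = chi_square_test(table)
                assoc[cov][name] = {
                    "statistic": stat,
                    "df": df,
                    "p": p,
                    "significant": bool(p < 0.05),
                    "table": table.to_dict(),
                }
            except ClinicalInputError as exc:  # degenerate margin
                assoc[cov][name] = {"error": str(exc)}
    report["associations"] = assoc

    # survival comparisons
    surv: dict = {}
    for which in ("os", "dfs"):
        surv[which] = {
            ma: _survival_block(records, labellings[ma], which),
            mb: _survival_block(records, labellings[mb], which),
            "combined_vs_rest": _survival_block(
                records, labellings[f"{ma}/{mb}"], which
            ),
            "four_group": _survival_block(records, groups, which),
        }
    report["survival"] = surv

    # extra markers across the four combined groups
    extra: dict = {}
    for m in extra_markers:
        lab_m = {r.patient_id: r.labels[m] for r in records}
        table = crosstab(lab_m, groups)
        try:
            stat, df, p = chi_square_test(table)
            chi_block = {"statistic": stat, "df": df, "p": p}
        except ClinicalInputError as exc:
            chi_block = {"error": str(exc)}
        irs_by_group: dict[str, list[int]] = {}
        for r in records:
            irs_by_group.setdefault(groups[r.patient_id], []).append(
                r.scores[m].irs
            )
        samples = [v for _, v in sorted(irs_by_group.items()) if len(v) > 0]
        if len(samples) >= 2:
            kw = stats.kruskal(*samples)
            kw_block = {"statistic": float(kw.statistic), "p": float(kw.pvalue)}
        else:
            kw_block = {"error": "fewer than two non-empty groups"}
        extra[m] = {
            "chi_square_on_labels": chi_block,
            "kruskal_wallis_on_irs": kw_block,
        }
    if extra:
        report["extra_markers"] = extra
    return report


def plot_km(
    records: Sequence[CohortRecord],
    group_of: Mapping[str, str],
    which: str,
    path: str | Path,
) -> None:  # pragma: no cover - optional plotting
    """Write a KM curve figure for one endpoint, one line per group (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    by_group: dict[str, tuple[list[float], list[bool]]] = {}
    for r in records:
        g = group_of[r.patient_id]
        t = r.time_os if which == "os" else r.time_dfs
        e = r.event_os if which == "os" else r.event_dfs
        by_group.setdefault(g, ([], []))[0].append(t)
        by_group[g][1].append(e)
    for g in sorted(by_group):
        kmf = KaplanMeierFitter()
        kmf.fit(*by_group[g], label=g)
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
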