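"""Condition-comparison statistics and the differential HDX-MS rule.

Two families live here:

* distribution comparison for per-frame distance series (two-sided
  Mann–Whitney U with an exact small-sample path, plus Tukey boxplot
  summaries), and
* the hydrogen/deuterium-exchange significance rule: a per-timepoint
  two-sample Student t test combined with a hard 0.2 Da floor — an uptake
  difference is called significant only when p < 0.05 AND |Δ| ≥ 0.2 Da —
  followed by a per-peptide increased/decreased/ns/mixed classification.

With two groups the pooled-variance Student t test and a one-way ANOVA are
the same test (F = t²), so the t statistic is what is implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataCompletenessError, EmptyInputError

__all__ = [
    "StatTestResult",
    "BoxSummary",
    "HDXPeptide",
    "HDXComparisonRow",
    "mann_whitney_u",
    "box_summary",
    "hdx_compare_peptide",
    "hdx_classify_regions",
    "read_hdx_csv",
    "comparison_to_frame",
    "HDX_MIN_DELTA_DA",
    "HDX_ALPHA",
]

#: Uptake differences smaller than this (Da) are never called significant.
HDX_MIN_DELTA_DA = 0.2
#: Per-timepoint significance level of the Student t test.
HDX_ALPHA = 0.05

#: Exact Mann–Whitney path bounds: enumeration is used when the smaller
#: sample has ≤ EXACT_MIN_N observations, there are no ties, and the larger
#: sample is small enough for the count table to stay cheap.
EXACT_MIN_N = 10
EXACT_MAX_N = 500


@dataclass(frozen=True)
class StatTestResult:
    statistic: float  # U for sample x
    p_value: float
    method: str  # "exact" | "normal-approximation"
    n1: int
    n2: int


@dataclass(frozen=True)
class BoxSummary:
    """Tukey boxplot summary (linear-interpolation quartiles, 1.5×IQR whiskers)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: #{x_i > y_j} + ½·#{x_i = y_j}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements per U value (no ties).

    ``counts[u]`` over u = 0..n1·n2, built with the standard recurrence
    c(m,n,u) = c(m−1,n,u−n) + c(m,n−1,u); total is C(n1+n2, n1).
    """
    u_max = n1 * n2
    # table[n][u] for current m
    table = np.zeros((n2 + 1, u_max + 1), dtype=float)
    table[:, 0] = 1.0
    for m in range(1, n1 + 1):
        new = np.zeros_like(table)
        new[0, 0] = 1.0
        for n in range(1, n2 + 1):
            new[n] = new[n - 1]
            new[n, n:] += table[n, : u_max + 1 - n]
        table = new
    return table[n2]


def mann_whitney_u(x: Iterable[float], y: Iterable[float]) -> StatTestResult:
    """Two-sided Mann–Whitney U test.

    Exact two-sided p by enumeration of the U distribution when the smaller
    sample has ≤ 10 observations and there are no ties; otherwise the normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise EmptyInputError("mann_whitney_u requires non-empty samples")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2

    if (
        not has_ties
        and min(n1, n2) <= EXACT_MIN_N
        and max(n1, n2) <= EXACT_MAX_N
    ):
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(u))
        u_low = min(u_int, n1 * n2 - u_int)
        # distribution is symmetric about n1·n2/2
        p = min(1.0, 2.0 * counts[: u_low + 1].sum() / total)
        return StatTestResult(u, float(p), "exact", n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return StatTestResult(u, 1.0, "normal-approximation", n1, n2)
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    # clamp away from exact zero (the survival function underflows for huge z)
    p = min(1.0, max(2.0 * sps.norm.sf(abs(z)), np.finfo(float).tiny))
    return StatTestResult(u, float(p), "normal-approximation", n1, n2)


# ---------------------------------------------------------------------------
# Box summary
# ---------------------------------------------------------------------------

def box_summary(values: Iterable[float]) -> BoxSummary:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise EmptyInputError("box_summary requires at least one value")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(o) for o in np.sort(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# HDX-MS
# ---------------------------------------------------------------------------

@dataclass
class HDXPeptide:
    """One peptic peptide's replicate uptake values (Da) per state and timepoint."""

    start_res: int
    end_res: int
    uptake: dict[str, dict[float, np.ndarray]]  # state → timepoint_s → replicates

    def __post_init__(self) -> None:
        if self.end_res < self.start_res:
            raise ValueError(
                f"peptide {self.start_res}-{self.end_res}: empty residue range"
            )
        for state, by_time in self.uptake.items():
            for t, vals in by_time.items():
                vals = np.asarray(vals, dtype=float)
                by_time[t] = vals
                if np.any(vals < 0):
                    raise ValueError(
                        f"peptide {self.start_res}-{self.end_res}, state {state}: "
                        "negative uptake"
                    )
            means = [by_time[t].mean() for t in sorted(by_time)]
            if any(b < a - 1e-9 for a, b in zip(means, means[1:])):
                warnings.warn(
                    f"peptide {self.start_res}-{self.end_res}, state {state}: "
                    "replicate-mean uptake is not non-decreasing in time",
                    stacklevel=2,
                )

    @property
    def label(self) -> str:
        return f"{self.start_res}-{self.end_res}"


@dataclass(frozen=True)
class HDXComparisonRow:
    start_res: int
    end_res: int
    timepoint_s: float
    delta_Da: float  # mean(state_b) − mean(state_a)
    p_value: float
    significant: bool


def _pooled_t_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p of the pooled-variance two-sample Student t test."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(2.0 * sps.t.sf(abs(t), na + nb - 2))


def hdx_compare_peptide(
    p: HDXPeptide,
    state_a: str,
    state_b: str,
    alpha: float = HDX_ALPHA,
    min_delta: float = HDX_MIN_DELTA_DA,
) -> list[HDXComparisonRow]:
    """Per-timepoint differential-uptake rows for one peptide.

    Δ = mean(state_b) − mean(state_a); a timepoint is significant only when
    the Student t test gives p < alpha AND |Δ| ≥ min_delta (0.2 Da by
    default) — small differences are never called significant, whatever
    their variance.
    """
    for state in (state_a, state_b):
        if state not in p.uptake:
            raise DataCompletenessError(
                f"peptide {p.label}: state {state!r} missing"
            )
    times_a = set(p.uptake[state_a])
    times_b = set(p.uptake[state_b])
    if times_a != times_b:
        raise DataCompletenessError(
            f"peptide {p.label}: timepoints differ between states "
            f"({sorted(times_a)} vs {sorted(times_b)})"
        )
    rows = []
    for t in sorted(times_a):
        a, b = p.uptake[state_a][t], p.uptake[state_b][t]
        if len(a) < 2 or len(b) < 2:
            raise DataCompletenessError(
                f"peptide {p.label}, t={t} s: need ≥2 replicates per state"
            )
        delta = float(b.mean() - a.mean())
        p_val = _pooled_t_test(a, b)
        rows.append(
            HDXComparisonRow(
                start_res=p.start_res,
                end_res=p.end_res,
                timepoint_s=float(t),
                delta_Da=delta,
                p_value=p_val,
                significant=bool(p_val < alpha and abs(delta) >= min_delta),
            )
        )
    return rows


def benjamini_hochberg(
    rows: list[HDXComparisonRow],
    alpha: float = HDX_ALPHA,
    min_delta: float = HDX_MIN_DELTA_DA,
) -> list[HDXComparisonRow]:
    """Optional FDR control across all peptide×timepoint comparisons.

    Returns new rows with Benjamini–Hochberg-adjusted p-values and
    significance recomputed (the |Δ| floor still applies).  Off by default
    in the pipeline: the standard workflow applies only the 0.2 Da floor.
    """
    if not rows:
        return []
    adjusted = sps.false_discovery_control([r.p_value for r in rows], method="bh")
    return [
        HDXComparisonRow(
            start_res=r.start_res,
            end_res=r.end_res,
            timepoint_s=r.timepoint_s,
            delta_Da=r.delta_Da,
            p_value=float(p_adj),
            significant=bool(p_adj < alpha and abs(r.delta_Da) >= min_delta),
        )
        for r, p_adj in zip(rows, adjusted)
    ]


def hdx_classify_regions(rows: list[HDXComparisonRow]) -> dict[str, str]:
    """Per-peptide class from its timepoint rows.

    "increased": ≥1 significant positive Δ and no significant negative;
    "decreased": the mirror; "ns": nothing significant; "mixed": both signs.
    """
    by_peptide: dict[str, list[HDXComparisonRow]] = {}
    for r in rows:
        by_peptide.setdefault(f"{r.start_res}-{r.end_res}", []).append(r)
    out = {}
    for label, rs in by_peptide.items():
        pos = any(r.significant and r.delta_Da > 0 for r in rs)
        neg = any(r.significant and r.delta_Da < 0 for r in rs)
        if pos and neg:
            out[label] = "mixed"
        elif pos:
            out[label] = "increased"
        elif neg:
            out[label] = "decreased"
        else:
            out[label] = "ns"
    return out


HDX_CSV_COLUMNS = [
    "peptide_start",
    "peptide_end",
    "state",
    "timepoint_s",
    "replicate",
    "uptake_Da",
]


def read_hdx_csv(path: str) -> list[HDXPeptide]:
    """Read the long-form uptake table (one row per replicate measurement)."""
    df = pd.read_csv(path)
    missing = [c for c in HDX_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataCompletenessError(
            f"{path}: missing required column(s) {missing}"
        )
    peptides = []
    for (start, end), grp in df.groupby(["peptide_start", "peptide_end"], sort=True):
        uptake: dict[str, dict[float, np.ndarray]] = {}
        for (state, t), g in grp.groupby(["state", "timepoint_s"], sort=True):
            uptake.setdefault(str(state), {})[float(t)] = (
                g.sort_values("replicate")["uptake_Da"].to_numpy(dtype=float)
            )
        peptides.append(HDXPeptide(start_res=int(start), end_res=int(end), uptake=uptake))
    return peptides


def comparison_to_frame(
    rows: list[HDXComparisonRow], classes: dict[str, str] | None = None
) -> pd.DataFrame:
    """Comparison rows (plus per-peptide class) as a tidy DataFrame."""
    classes = classes or hdx_classify_regions(rows)
    return pd.DataFrame(
        {
            "peptide_start": [r.start_res for r in rows],
            "peptide_end": [r.end_res for r in rows],
            "timepoint_s": [r.timepoint_s for r in rows],
            "delta_Da": [r.delta_Da for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "class": [classes[f"{r.start_res}-{r.end_res}"] for r in rows],
        }
    )
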