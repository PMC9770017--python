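"""Group statistics over triads: Friedman, Bonferroni post hoc, effect tables.

For each variable and stimulation phase the per-animal means over valid
triads form an animals x 3 matrix (control, stimulated, post cycles). The
repeated-measures comparison across the three cycles uses the Friedman rank
test (animals as blocks, average ranks and tie correction); when the main
effect is significant, Bonferroni-adjusted Wilcoxon signed-rank tests
compare the stimulated and post cycles against control. Normality
(Shapiro-Wilk) is reported but never gates the nonparametric test. Percent
changes are computed per animal against its own control mean, then averaged
across animals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .io_core import PHASES
from .phase_windows import CYCLE_POSITIONS

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate(metrics: pd.DataFrame, variable: str, phase: str,
              limb: str | None = None) -> pd.DataFrame:
    """Per-animal means of one variable per cycle position, animals as rows.

    Animals without a single valid triad for this variable/phase are dropped.
    Returns a DataFrame with columns ``control, stim, post`` (NaN where an
    animal has no value for that position).
    """
    sel = (metrics["variable"] == variable) & (metrics["phase"] == phase)
    if limb is not None:
        sel &= metrics["limb"] == limb
    sub = metrics.loc[sel]
    if sub.empty:
        return pd.DataFrame(columns=list(CYCLE_POSITIONS))
    mat = (sub.groupby(["animal", "position"])["value"].mean()
           .unstack("position").reindex(columns=list(CYCLE_POSITIONS)))
    return mat.dropna(how="all")


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p; (nan, nan) for a constant sample."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if values.size > 5000:
        raise ValueError("Shapiro-Wilk is defined for n <= 5000")
    if np.ptp(values) == 0:
        return float("nan"), float("nan")
    w, p = spstats.shapiro(values)
    return float(w), float(p)


def friedman_statistic(matrix: np.ndarray) -> float:
    """Friedman chi-square statistic with average ranks and tie correction."""
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    n, k = x.shape
    ranks = np.apply_along_axis(spstats.rankdata, 1, x)
    rj = ranks.sum(axis=0)
    a = float(np.sum(ranks ** 2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every row fully tied
        return 0.0
    return float((k - 1) * np.sum((rj - n * (k + 1) / 2.0) ** 2) / (a - c))


def exact_friedman_pvalue(statistic: float, n: int, k: int = 3) -> float:
    """Exact permutation tail P(Q >= statistic) for k = 3, untied rows.

    Dynamic programme over the joint distribution of the first two column
    rank sums; feasible for any realistic block count.
    """
    if k != 3:
        raise ValueError("exact tail implemented for k = 3 only")
    from itertools import permutations
    perms = list(permutations((1, 2, 3)))
    dist: dict[tuple[int, int], float] = {(0, 0): 1.0}
    for _ in range(n):
        new: dict[tuple[int, int], float] = {}
        for (r1, r2), p in dist.items():
            for perm in perms:
                key = (r1 + perm[0], r2 + perm[1])
                new[key] = new.get(key, 0.0) + p / 6.0
        dist = new
    tail = 0.0
    for (r1, r2), p in dist.items():
        r3 = 6 * n - r1 - r2
        q = (12.0 / (n * 3 * 4)) * (r1**2 + r2**2 + r3**2) - 3 * n * 4
        if q >= statistic - 1e-9:
            tail += p
    return float(tail)


def friedman_test(matrix: np.ndarray, method: str = "chi2"
                  ) -> tuple[float, int, float]:
    """(statistic, df, p) for the Friedman test across columns.

    Rows with missing entries are excluded. ``method='chi2'`` uses the
    standard chi-square approximation; ``'exact'`` the exact permutation
    tail (k = 3, no ties).
    """
    x = np.asarray(matrix, float)
    x = x[np.all(np.isfinite(x), axis=1)]
    if x.shape[0] < 2:
        raise ValueError("Friedman test needs at least 2 complete rows")
    k = x.shape[1]
    stat = friedman_statistic(x)
    df = k - 1
    if method == "chi2":
        p = float(spstats.chi2.sf(stat, df))
    elif method == "exact":
        p = exact_friedman_pvalue(stat, x.shape[0], k)
    else:
        raise ValueError(f"unknown method {method!r}")
    return stat, df, p


def bonferroni_posthoc(matrix: pd.DataFrame | np.ndarray,
                       comparisons: tuple[tuple[str, str], ...] = (
                           ("stim", "control"), ("post", "control")),
                       ) -> dict[str, float]:
    """Bonferroni-adjusted pairwise Wilcoxon signed-rank tests.

    Raw two-sided p-values are multiplied by the number of reported
    comparisons and capped at 1. All-zero difference vectors give p = 1.
    """
    if isinstance(matrix, np.ndarray):
        matrix = pd.DataFrame(matrix, columns=list(CYCLE_POSITIONS))
    m = len(comparisons)
    out = {}
    for a, b in comparisons:
        pair = matrix[[a, b]].dropna()
        diff = pair[a].to_numpy() - pair[b].to_numpy()
        if diff.size < 1 or np.all(diff == 0):
            out[f"{a}_vs_{b}"] = 1.0
            continue
        res = spstats.wilcoxon(diff, zero_method="wilcox",
                               alternative="two-sided")
        out[f"{a}_vs_{b}"] = float(min(1.0, m * res.pvalue))
    return out


def percent_change(matrix: pd.DataFrame | np.ndarray
                   ) -> dict[str, tuple[float, float]]:
    """Group mean +- SD of per-animal percent changes vs control.

    Raises if any control entry is non-positive (the percentage is undefined).
    """
    if isinstance(matrix, np.ndarray):
        matrix = pd.DataFrame(matrix, columns=list(CYCLE_POSITIONS))
    ctrl = matrix["control"].to_numpy(float)
    if np.any(~np.isfinite(ctrl)) or np.any(ctrl <= 0):
        raise ValueError("percent change requires positive control means")
    out = {}
    for pos in ("stim", "post"):
        pct = 100.0 * (matrix[pos].to_numpy(float) - ctrl) / ctrl
        pct = pct[np.isfinite(pct)]
        out[pos] = (float(np.mean(pct)), float(np.std(pct, ddof=1))
                    if pct.size > 1 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Effect tables and report
# ---------------------------------------------------------------------------


@dataclass
class PhaseEffectTable:
    variable: str
    limb: str
    phase: str
    matrix: pd.DataFrame  # animals x (control, stim, post)
    group_mean: dict[str, float] = field(default_factory=dict)
    group_sd: dict[str, float] = field(default_factory=dict)
    pct_change: dict[str, tuple[float, float]] = field(default_factory=dict)
    shapiro: dict[str, tuple[float, float]] = field(default_factory=dict)
    friedman: tuple[float, int, float] | None = None
    posthoc: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.friedman is not None and self.friedman[2] < ALPHA


def build_table(metrics: pd.DataFrame, variable: str, phase: str,
                limb: str | None = None) -> PhaseEffectTable | None:
    """Full statistics for one variable in one phase; None if < 2 animals."""
    mat = aggregate(metrics, variable, phase, limb)
    complete = mat.dropna()
    if complete.shape[0] < 2:
        return None
    table = PhaseEffectTable(variable=variable, limb=limb or "", phase=phase,
                             matrix=mat)
    for pos in CYCLE_POSITIONS:
        vals = complete[pos].to_numpy(float)
        table.group_mean[pos] = float(np.mean(vals))
        table.group_sd[pos] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        if vals.size >= 3:
            table.shapiro[pos] = shapiro_wilk(vals)
    try:
        table.pct_change = percent_change(complete)
    except ValueError:
        table.pct_change = {}
    table.friedman = friedman_test(complete.to_numpy(float))
    if table.significant:
        table.posthoc = bonferroni_posthoc(complete)
    return table


def tables_to_frame(tables: list[PhaseEffectTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        row = {
            "variable": t.variable, "limb": t.limb, "phase": t.phase,
            "n_animals": int(t.matrix.dropna().shape[0]),
        }
        for pos in CYCLE_POSITIONS:
            row[f"{pos}_mean"] = t.group_mean.get(pos, np.nan)
            row[f"{pos}_sd"] = t.group_sd.get(pos, np.nan)
        for pos in ("stim", "post"):
            pc = t.pct_change.get(pos)
            row[f"pct_{pos}"] = pc[0] if pc else np.nan
            row[f"pct_{pos}_sd"] = pc[1] if pc else np.nan
        if t.friedman:
            row["friedman_chi2"], row["friedman_df"], row["friedman_p"] = t.friedman
        row["p_stim_vs_control"] = t.posthoc.get("stim_vs_control", np.nan)
        row["p_post_vs_control"] = t.posthoc.get("post_vs_control", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(tables: list[PhaseEffectTable], out_dir: str | Path,
                 plots: bool = False) -> pd.DataFrame:
    """Write per-phase effect tables (TSV) and a machine-readable stats.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = tables_to_frame(tables)
    for phase in PHASES:
        sub = frame[frame["phase"] == phase] if not frame.empty else frame
        sub.to_csv(out / f"effects_{phase}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    payload = json.loads(frame.to_json(orient="records")) if not frame.empty else []
    (out / "stats.json").write_text(json.dumps(payload, indent=1))
    if plots and not frame.empty:
        _plot_report(tables, out)
    return frame


def _plot_report(tables: list[PhaseEffectTable], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_phase: dict[str, list[PhaseEffectTable]] = {}
    for t in tables:
        by_phase.setdefault(t.phase, []).append(t)
    for phase, ts in by_phase.items():
        ts = ts[:30]
        fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(ts)), 4))
        xs = np.arange(len(ts))
        for j, pos in enumerate(CYCLE_POSITIONS):
            means = [t.group_mean.get(pos, np.nan) for t in ts]
            sds = [t.group_sd.get(pos, np.nan) for t in ts]
            ax.errorbar(xs + 0.2 * (j - 1), means, yerr=sds, fmt="o",
                        ms=3, label=pos)
        for j, t in enumerate(ts):
            if t.posthoc.get("stim_vs_control", 1.0) < ALPHA:
                ax.annotate("*", (xs[j], ax.get_ylim()[1]), ha="center")
        ax.set_xticks(xs)
        ax.set_xticklabels([f"{t.variable}\n{t.limb}" for t in ts],
                           rotation=90, fontsize=6)
        ax.set_title(phase)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"effects_{phase}.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def null_matrix(n_animals: int, n_triads: int, rng: np.random.Generator,
                between_sigma: float = 0.05, within_sigma: float = 0.1
                ) -> np.ndarray:
    """One animals x 3 matrix of per-animal triad means under the null.

    Each animal has a multiplicative log-normal level; triad values share no
    cycle-position effect, so the three columns are exchangeable.
    """
    base = np.exp(rng.normal(0.0, between_sigma, size=n_animals))
    vals = base[:, None, None] * (
        1.0 + within_sigma * rng.standard_normal((n_animals, 3, n_triads)))
    return vals.mean(axis=2)


def friedman_type1_error(n_reps: int = 2000, n_animals: int = 7,
                         n_triads: int = 10,
                         rng: np.random.Generator | None = None,
                         alpha: float = ALPHA) -> float:
    """Empirical rejection rate of the Friedman test on null matrices."""
    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    for _ in range(n_reps):
        m = null_matrix(n_animals, n_triads, rng)
        _, _, p = friedman_test(m)
        hits += p < alpha
    return hits / n_reps
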