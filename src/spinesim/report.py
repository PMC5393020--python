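"""Cohort-level outputs: corrected-index tables, pooled bone-screw force
summaries per screw pattern, and pattern comparison statistics.

Pooling convention: per pattern, the forces of all screws of all cases are
pooled (matching how min-max spreads are reported for constructs).  The
primary comparison is a Welch two-sample t-test on pooled per-screw forces;
a paired t-test on per-case mean forces is reported as a sensitivity
output.  The choice of test is labeled in the output because different
conventions exist.  Raw p-values are primary; Holm-adjusted values are
reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CohortSummary", "summarize_cohort", "compare_patterns",
           "pooled_force_stats"]

_INDEX_COLS = ["pt_cobb", "mt_cobb", "tll_cobb", "kyphosis", "lordosis",
               "mt_avr", "tll_avr"]


def pooled_force_stats(magnitudes) -> dict:
    """(mean, sd, min, max, n) of a pooled force sample."""
    m = np.asarray(magnitudes, dtype=float)
    if m.size == 0:
        return {"mean": 0.0, "sd": 0.0, "min": 0.0, "max": 0.0, "n": 0}
    return {"mean": float(m.mean()),
            "sd": float(m.std(ddof=1)) if m.size > 1 else 0.0,
            "min": float(m.min()), "max": float(m.max()),
            "n": int(m.size)}


@dataclass
class CohortSummary:
    """All cohort outputs in tabular form."""

    indices: pd.DataFrame          # case x pattern corrected indices (+preop)
    forces: pd.DataFrame           # per-screw forces, all cases/patterns
    force_stats: pd.DataFrame      # per-pattern pooled stats
    reductions: pd.DataFrame       # per-construct screw-count stats
    missing: list = field(default_factory=list)   # (case, pattern) not run

    def validate(self):
        fs = self.force_stats
        if (fs["sd"] < 0).any():
            raise ValueError("negative SD in force stats")
        bad = ~((fs["min"] <= fs["mean"] + 1e-9)
                & (fs["mean"] <= fs["max"] + 1e-9))
        if bad.any():
            raise ValueError("force stats violate min <= mean <= max")
        return self


def summarize_cohort(results: dict, preop_reports: dict | None = None,
                     patterns: dict | None = None) -> CohortSummary:
    """Aggregate simulation results into a cohort summary.

    ``results``: {(case_id, pattern_id): SimulationResult}.
    ``preop_reports``: optional {case_id: IndexReport} measured on the
    preoperative geometries.  ``patterns``: optional
    {case_id: {pattern_id: ScrewPattern}} for the reduction table.
    Missing (case, pattern) combinations are flagged, not invented.
    """
    cases = sorted({c for c, _ in results}, key=str)
    pids = sorted({p for _, p in results})

    idx_rows, force_rows, missing = [], [], []
    for case in cases:
        if preop_reports and case in preop_reports:
            rep = preop_reports[case]
            idx_rows.append({"case_id": case, "pattern": "preop",
                             **{k: round(getattr(rep, k), 2)
                                for k in _INDEX_COLS}})
        for pid in pids:
            res = results.get((case, pid))
            if res is None:
                missing.append((case, pid))
                continue
            row = {"case_id": case, "pattern": pid,
                   "converged": res.converged,
                   "max_gap_mm": round(res.max_gap_mm, 4)}
            if res.report is not None:
                row.update({k: round(getattr(res.report, k), 2)
                            for k in _INDEX_COLS})
            idx_rows.append(row)
            for s in res.screw_forces:
                force_rows.append({"case_id": case, "pattern": pid, **s})

    indices = pd.DataFrame(idx_rows)
    forces = pd.DataFrame(force_rows)
    stats_rows = []
    for pid in pids:
        sub = forces[forces["pattern"] == pid]["magnitude"] \
            if len(forces) else []
        stats_rows.append({"pattern": pid,
                           **pooled_force_stats(np.asarray(sub))})
    force_stats = pd.DataFrame(stats_rows)

    red_rows = []
    if patterns:
        for case, pats in patterns.items():
            for pid, pat in sorted(pats.items()):
                red_rows.append({"case_id": case, "pattern": pid,
                                 "n_screws": pat.n_screws,
                                 "n_dropped": len(pat.dropouts),
                                 "reduction_pct": round(pat.reduction_pct, 2),
                                 "density": round(pat.density, 3)})
    reductions = pd.DataFrame(red_rows)
    return CohortSummary(indices, forces, force_stats, reductions,
                         missing).validate()


def _welch(a, b):
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    if np.allclose(a, b[:len(a)] if len(a) == len(b) else a.mean()) \
            and np.isclose(np.std(a), 0) and np.isclose(np.std(b), 0) \
            and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t) and np.isclose(a.mean(), b.mean()):
        return 0.0, 1.0
    return float(t), float(p)


def compare_patterns(summary: CohortSummary,
                     alternate=(2, 3), periapical=(4, 5)) -> pd.DataFrame:
    """All pairwise pattern comparisons plus alternate-vs-periapical.

    Primary: Welch two-sample t on pooled per-screw force magnitudes.
    Sensitivity: paired t on per-case mean forces.  Both raw and
    Holm-adjusted p-values are reported.
    """
    forces = summary.forces
    pids = sorted(forces["pattern"].unique())
    samples = {p: forces.loc[forces["pattern"] == p, "magnitude"].to_numpy()
               for p in pids}
    case_means = {
        p: forces[forces["pattern"] == p]
        .groupby("case_id")["magnitude"].mean() for p in pids}

    rows = []

    def add_row(name, a, b, paired_a=None, paired_b=None):
        t, p = _welch(a, b)
        row = {"comparison": name,
               "mean_diff_N": float(np.mean(a) - np.mean(b))
               if len(a) and len(b) else np.nan,
               "test": "welch_t_pooled_screws",
               "t": t, "p": p}
        if paired_a is not None:
            common = paired_a.index.intersection(paired_b.index)
            if len(common) >= 2:
                d = paired_a[common] - paired_b[common]
                if np.allclose(d, 0):
                    row["paired_t"], row["paired_p"] = 0.0, 1.0
                else:
                    pt, pp = stats.ttest_rel(paired_a[common],
                                             paired_b[common])
                    row["paired_t"], row["paired_p"] = float(pt), float(pp)
        rows.append(row)

    for a, b in combinations(pids, 2):
        add_row(f"pattern{a}_vs_pattern{b}", samples[a], samples[b],
                case_means[a], case_means[b])
    alt = np.concatenate([samples[p] for p in alternate if p in samples]) \
        if any(p in samples for p in alternate) else np.array([])
    peri = np.concatenate([samples[p] for p in periapical if p in samples]) \
        if any(p in samples for p in periapical) else np.array([])
    if len(alt) and len(peri):
        add_row("alternate_vs_periapical", alt, peri)

    if not rows:                      # fewer than two patterns simulated
        return pd.DataFrame(columns=["comparison", "mean_diff_N", "test",
                                     "t", "p", "paired_t", "paired_p",
                                     "p_holm"])
    out = pd.DataFrame(rows)
    # Holm adjustment of the raw Welch p-values (reported alongside)
    pvals = out["p"].to_numpy()
    ok = ~np.isnan(pvals)
    adj = np.full_like(pvals, np.nan)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests
        adj[ok] = multipletests(pvals[ok], method="holm")[1]
    out["p_holm"] = adj
    return out


def plot_force_summary(summary: CohortSummary, path):
    """Bar chart of per-pattern mean bone-screw force with min-max bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fs = summary.force_stats
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(fs))
    ax.bar(x, fs["mean"], color="#4878a8")
    ax.errorbar(x, fs["mean"],
                yerr=[fs["mean"] - fs["min"], fs["max"] - fs["mean"]],
                fmt="none", ecolor="k", capsize=4)
    ax.set_xticks(x)
    ax.set_xticklabels([f"pattern {p}" for p in fs["pattern"]])
    ax.set_ylabel("bone-screw force (N)")
    ax.set_title("Average (bars = min, max) bone-screw forces")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
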