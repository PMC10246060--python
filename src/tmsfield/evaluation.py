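"""Timing summaries, the independent-samples t-test, and the benchmark report.

Two kinds of numbers live here. Live timings come from the streaming loop's
per-run records (E-field prediction vs. visualization/transmit seconds),
summarized as mean ± sample standard deviation over a fixed number of runs
(50 by default). The packaged benchmark fixture is a transcription of
published visualization timings for ten subjects on two CPU machines with two
tools — a FEM-based visualizer ("simnibs") and a real-time deep-learning
predictor ("realtime") — and everything derived from it is exact arithmetic
on those printed numbers, with no hardware dependence.

The fixture's printed per-subject mean and improvement columns contain small
anomalies (a per-subject "mean" that equals one machine's cell, improvement
factors that are not exactly the ratio of the printed means); they are
preserved verbatim, and the report carries both the as-printed values and the
recomputed ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TimingSummary",
    "BenchmarkFixture",
    "TTestResult",
    "load_benchmark_fixture",
    "time_pipeline",
    "two_sample_ttest",
    "reproduce_table2",
]


@dataclass
class TimingSummary:
    """Mean ± sample std seconds per pipeline component over ``n_runs`` runs."""

    cnn_mean: float
    cnn_std: float
    vis_mean: float
    vis_std: float
    n_runs: int

    def as_dict(self) -> dict:
        return {
            "cnn_mean_s": self.cnn_mean, "cnn_std_s": self.cnn_std,
            "vis_mean_s": self.vis_mean, "vis_std_s": self.vis_std,
            "n_runs": self.n_runs,
        }


@dataclass
class BenchmarkFixture:
    """10 subjects x 2 machines x 2 tools of visualization seconds (long form)."""

    times: pd.DataFrame          # columns: subject, machine, tool, seconds
    printed: pd.DataFrame        # per-subject printed means and improvement factors

    def __post_init__(self) -> None:
        need = {"subject", "machine", "tool", "seconds"}
        if not need.issubset(self.times.columns):
            raise ValueError(f"fixture needs columns {sorted(need)}")
        counts = self.times.groupby(["tool", "machine"]).size()
        if len(self.times) != 40 or counts.nunique() != 1 or counts.iloc[0] != 10:
            raise ValueError("fixture must be a complete 10x2x2 grid (40 rows)")
        if (self.times["seconds"] <= 0).any():
            raise ValueError("all times must be positive")

    def tool_seconds(self, tool: str) -> np.ndarray:
        sel = self.times[self.times["tool"] == tool]
        return sel.sort_values(["machine", "subject"])["seconds"].to_numpy()


def load_benchmark_fixture() -> BenchmarkFixture:
    """Load the packaged benchmark transcription."""
    base = resources.files("tmsfield") / "data"
    times = pd.read_csv(str(base / "benchmark_timings.csv"))
    printed = pd.read_csv(str(base / "benchmark_printed.csv"))
    return BenchmarkFixture(times=times, printed=printed)


def time_pipeline(session, runs: int = 50) -> TimingSummary:
    """Summarize the first ``runs`` per-run records of a streaming session.

    ``session`` is a :class:`tmsfield.streaming.SessionStats` or any object
    with a ``runs`` list of ``{"cnn_seconds", "vis_seconds"}`` records.
    Raises if fewer records than ``runs`` are available.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    records = session.runs if hasattr(session, "runs") else list(session)
    if len(records) < runs:
        raise ValueError(f"need {runs} run records, have {len(records)}")
    cnn = np.array([r["cnn_seconds"] for r in records[:runs]], dtype=float)
    vis = np.array([r["vis_seconds"] for r in records[:runs]], dtype=float)
    sd = lambda v: float(np.std(v, ddof=1)) if runs > 1 else 0.0
    return TimingSummary(
        cnn_mean=float(cnn.mean()), cnn_std=sd(cnn),
        vis_mean=float(vis.mean()), vis_std=sd(vis),
        n_runs=runs,
    )


@dataclass
class TTestResult:
    t: float
    df: int
    p: float                    # two-sided
    mean_a: float
    mean_b: float
    std_a: float
    std_b: float
    infinite: bool = False      # zero pooled variance with unequal means


def two_sample_ttest(a, b) -> TTestResult:
    """Pooled-variance (Student) two-sided independent-samples t-test.

    t = (mean_a - mean_b) / (s_p * sqrt(1/n1 + 1/n2)) with the pooled variance
    s_p^2 = ((n1-1) s_a^2 + (n2-1) s_b^2) / (n1 + n2 - 2) and df = n1+n2-2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, a.mean(), b.mean(), 0.0, 0.0)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0,
                           a.mean(), b.mean(), 0.0, 0.0, infinite=True)
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return TTestResult(float(t), int(df), p, float(a.mean()), float(b.mean()),
                       float(np.sqrt(va)), float(np.sqrt(vb)))


def reproduce_table2(fixture: BenchmarkFixture | None = None) -> dict:
    """Recompute the benchmark comparison from the packaged fixture.

    Returns a report dict with pooled per-tool means ± std over all 20 cells,
    per-subject improvement factors (both as printed and recomputed from the
    printed per-subject means), their means, and the pooled two-sample t-test.
    """
    if fixture is None:
        fixture = load_benchmark_fixture()
    sim = fixture.tool_seconds("simnibs")
    rt = fixture.tool_seconds("realtime")
    tt = two_sample_ttest(sim, rt)

    per_subj = fixture.printed.copy()
    per_subj["improvement_recomputed"] = (
        per_subj["simnibs_mean_s"] / per_subj["realtime_mean_s"]
    )
    report = {
        "simnibs_mean_s": float(sim.mean()),
        "simnibs_std_s": float(sim.std(ddof=1)),
        "realtime_mean_s": float(rt.mean()),
        "realtime_std_s": float(rt.std(ddof=1)),
        "improvement_printed_mean": float(per_subj["improvement_factor"].mean()),
        "improvement_recomputed_mean": float(per_subj["improvement_recomputed"].mean()),
        "pooled_mean_ratio": float(sim.mean() / rt.mean()),
        "t_statistic": tt.t,
        "t_df": tt.df,
        "t_p_two_sided": tt.p,
        "per_subject": per_subj,
    }
    return report


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit the benchmark report as CSV + plain text; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "benchmark_report.csv"
    txt_path = out_dir / "benchmark_report.txt"
    report["per_subject"].to_csv(csv_path, index=False)
    scalars = {k: v for k, v in report.items() if k != "per_subject"}
    lines = ["benchmark comparison (packaged fixture, 10 subjects x 2 machines)"]
    lines += [f"  {k} = {v:.6g}" for k, v in scalars.items()]
    lines.append(
        f"  => pooled t({report['t_df']}) = {report['t_statistic']:.1f}, "
        f"p = {report['t_p_two_sided']:.3g}; "
        f"mean speed-up (printed column) {report['improvement_printed_mean']:.2f}x"
    )
    txt_path.write_text("\n".join(lines) + "\n")
    return csv_path, txt_path
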