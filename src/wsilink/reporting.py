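"""Distributional summaries and export of attack success rates.

Repeated experiments yield a sample of R_s values per condition; these are
summarised without normality assumptions — median, quartiles and the true
min–max range (no outlier trimming) — plus a percentile-bootstrap 95%
confidence interval for the median.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .attack import RsResult

__all__ = [
    "SummaryStats",
    "summarize_samples",
    "bootstrap_ci",
    "results_to_frame",
    "export_results",
    "read_results",
    "plot_rs_box",
]

RESULT_COLUMNS = [
    "experiment", "repeat", "extractor", "measure", "rs", "n_vulnerable", "n_patients",
]


@dataclass(frozen=True)
class SummaryStats:
    median: float
    q1: float
    q3: float
    min: float
    max: float
    ci95_low: float
    ci95_high: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("order statistics out of order")


def bootstrap_ci(
    samples: Sequence[float],
    statistic=np.median,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile-bootstrap 95% interval of ``statistic``, deterministic per seed."""
    x = np.sort(np.asarray(samples, dtype=float))  # order-free resampling
    if x.size < 2:
        raise ValueError("bootstrap needs at least 2 samples")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    stats = np.array(
        [statistic(x[rng.integers(0, x.size, size=x.size)]) for _ in range(n_boot)]
    )
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def summarize_samples(
    samples: Sequence[float], *, n_boot: int = 1000, seed: int = 0
) -> SummaryStats:
    """Five-number summary (type-7 linear-interpolation quartiles, untrimmed
    extremes) plus a bootstrap CI for the median."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if x.size >= 2:
        lo, hi = bootstrap_ci(x, np.median, n_boot=n_boot, seed=seed)
    else:
        lo = hi = float(med)
    return SummaryStats(
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(x.min()), max=float(x.max()),
        ci95_low=lo, ci95_high=hi, n_samples=int(x.size),
    )


def results_to_frame(
    results: Sequence[RsResult],
    *,
    experiment: str,
    extractor: str,
    measure: str,
) -> pd.DataFrame:
    rows = [
        {
            "experiment": experiment,
            "repeat": i,
            "extractor": extractor,
            "measure": measure,
            "rs": r.rs,
            "n_vulnerable": r.n_vulnerable,
            "n_patients": r.n_patients,
        }
        for i, r in enumerate(results)
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def export_results(
    frame: Union[pd.DataFrame, Sequence[RsResult]],
    path: Union[str, Path],
    *,
    experiment: Optional[str] = None,
    extractor: Optional[str] = None,
    measure: Optional[str] = None,
    summary_seed: int = 0,
) -> Path:
    """Write one row per repeat plus a commented summary block.

    Floats are printed with 12 significant digits so a read-back reproduces
    the values losslessly at that precision.  A raw result list may be passed
    together with its provenance labels.
    """
    if not isinstance(frame, pd.DataFrame):
        if experiment is None or extractor is None or measure is None:
            raise ValueError("raw results need experiment/extractor/measure labels")
        frame = results_to_frame(
            frame, experiment=experiment, extractor=extractor, measure=measure
        )
    if frame.empty:
        raise ValueError("refusing to export an empty result set")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        frame.to_csv(fh, index=False, float_format="%.12g")
        for exp, grp in frame.groupby("experiment", sort=False):
            s = summarize_samples(grp["rs"].to_numpy(), seed=summary_seed)
            stats = ",".join(f"{f.name}={getattr(s, f.name):.12g}" for f in fields(s))
            fh.write(f"# summary,{exp},{stats}\n")
    return path


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read the per-repeat rows back (the summary block is comment-skipped)."""
    return pd.read_csv(path, comment="#")


def plot_rs_box(
    groups: Dict[str, Sequence[float]],
    path: Union[str, Path],
    *,
    xlabel: str = "condition",
    seed: int = 0,
) -> Path:
    """Box plot per condition — median, quartiles, min–max whiskers (no
    outlier trimming) — with dashed tabs at the bootstrap 95% CI of the median."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(labels), 4.0))
    ax.boxplot(data, tick_labels=labels, whis=(0, 100), showfliers=False)
    for i, x in enumerate(data, start=1):
        if x.size >= 2:
            lo, hi = bootstrap_ci(x, np.median, seed=seed)
            ax.hlines([lo, hi], i - 0.3, i + 0.3, linestyles="dashed", colors="tab:red")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(r"$R_s$")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
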