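"""Multi-run trial protocol and nonparametric comparison statistics.

The benchmarking protocol: every (algorithm, function) cell is a vector of
final best fitnesses over independent seeded runs (seeds ``base_seed ..
base_seed + n_runs - 1``), summarised as Avg/Std.  Pairwise differences are
judged with the Wilcoxon signed-rank test at the 0.05 level ("+/=/-"
labels) and overall behaviour with Friedman average rank values (ARV,
ranking algorithms per function by Avg, lower is better).

Externally produced result vectors (e.g. for competitor algorithms run
elsewhere) can be injected into a :class:`TrialTable` from CSV and compared
with the same statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .glsma import GLSMAConfig, run_glsma
from .sma import OptimizerConfig, run_sma

__all__ = [
    "TrialTable",
    "ALGORITHMS",
    "run_trials",
    "wilcoxon_signed_rank",
    "friedman_average_ranks",
    "summarize",
]

ALPHA = 0.05


def _variant_cfg(algo: str, cfg: GLSMAConfig) -> GLSMAConfig:
    flags = {
        "sma": dict(gaussian=False, levy=False),
        "gsma": dict(gaussian=True, levy=False),
        "lsma": dict(gaussian=False, levy=True),
        "glsma": dict(gaussian=True, levy=True),
    }
    try:
        return replace(cfg, **flags[algo])
    except KeyError:
        raise ValueError(f"unknown algorithm {algo!r}; expected one of {sorted(flags)}") from None


ALGORITHMS = ("sma", "gsma", "lsma", "glsma")


@dataclass
class TrialTable:
    """Final-best-fitness vectors per (algorithm, function)."""

    algorithms: List[str]
    functions: List[str]
    results: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)
    runs: int = 30

    def add(self, algorithm: str, function: str, values: Sequence[float]) -> None:
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("result vector must be 1-D and non-empty")
        self.results[(algorithm, function)] = v

    def validate(self) -> None:
        lengths = set()
        for a in self.algorithms:
            for f in self.functions:
                if (a, f) not in self.results:
                    raise ValueError(f"missing cell ({a}, {f})")
                lengths.add(self.results[(a, f)].size)
        if len(lengths) > 1:
            raise ValueError(f"unequal result-vector lengths: {sorted(lengths)}")

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        """Load cells from a CSV with columns algorithm, function, run, value."""
        df = pd.read_csv(path)
        need = {"algorithm", "function", "value"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        algos = sorted(df["algorithm"].unique())
        funcs = sorted(df["function"].unique())
        t = cls(algorithms=algos, functions=funcs)
        for (a, f), grp in df.groupby(["algorithm", "function"]):
            t.add(a, f, grp["value"].to_numpy())
        return t


def run_trials(
    algorithm: str,
    function,
    cfg: Optional[GLSMAConfig] = None,
    n_runs: int = 30,
    base_seed: int = 1,
    trace_dir: Optional[Path] = None,
) -> np.ndarray:
    """Final best fitnesses of ``algorithm`` on ``function`` over seeded runs.

    Seeds ``base_seed .. base_seed + n_runs - 1``; convergence traces go to
    ``trace_dir`` as one CSV per run when given.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = _variant_cfg(algorithm, cfg or GLSMAConfig())
    finals = np.empty(n_runs)
    for i in range(n_runs):
        res = run_glsma(function, replace(cfg, seed=base_seed + i))
        finals[i] = res.best_f
        if trace_dir is not None:
            trace_dir = Path(trace_dir)
            trace_dir.mkdir(parents=True, exist_ok=True)
            name = getattr(function, "name", "objective")
            pd.DataFrame(
                {"iteration": np.arange(1, res.trace.size + 1),
                 "best_fitness": res.trace}
            ).to_csv(trace_dir / f"{algorithm}_{name}_seed{base_seed + i}.csv", index=False)
    return finals


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], zero_method: str = "wilcox"
) -> Tuple[float, str]:
    """Two-sided Wilcoxon signed-rank p-value and a "+/=/-" label at 0.05.

    Zero differences are dropped (``zero_method="pratt"`` keeps them in the
    ranking); fewer than 5 informative pairs yields ("=", p = 1).  The label
    is "+" when ``a`` is significantly better (smaller) than ``b``, "-" when
    significantly worse.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nz = d[d != 0.0]
    if nz.size < 5:
        return 1.0, "="
    # exact distribution only without ties among |d|
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "approx" if (nz.size > 25 or has_ties) else "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat_res = stats.wilcoxon(
            a, b, zero_method=zero_method, alternative="two-sided",
            correction=False, method=method,
        )
    p = float(stat_res.pvalue)
    if p >= ALPHA:
        return p, "="
    return p, ("+" if np.median(nz) < 0 else "-")


def friedman_average_ranks(avg_table: pd.DataFrame) -> pd.Series:
    """Friedman average rank values: mean per-function rank of each algorithm.

    ``avg_table`` is functions x algorithms (Avg values, minimization);
    ties get mid-ranks.  ARVs over k algorithms sum to k(k+1)/2 per row.
    """
    if avg_table.shape[1] < 2:
        raise ValueError("need at least 2 algorithms to rank")
    ranks = avg_table.rank(axis=1, method="average", ascending=True)
    return ranks.mean(axis=0).rename("ARV")


def summarize(table: TrialTable, out_dir: Optional[Path] = None,
              reference: Optional[str] = None) -> Dict[str, pd.DataFrame]:
    """Avg/Std per cell, best-marking, pairwise Wilcoxon vs a reference
    algorithm, and the Friedman ARV ranking.

    Returns the report frames; with ``out_dir`` also writes them as CSV and
    a Markdown digest.  ``reference`` defaults to the first algorithm.
    """
    table.validate()
    avg = pd.DataFrame(index=table.functions, columns=table.algorithms, dtype=float)
    std = pd.DataFrame(index=table.functions, columns=table.algorithms, dtype=float)
    for (a, f), v in table.results.items():
        avg.loc[f, a] = v.mean()
        std.loc[f, a] = v.std(ddof=0)
    best = avg.idxmin(axis=1).rename("best")

    out: Dict[str, pd.DataFrame] = {"avg": avg, "std": std, "best": best.to_frame()}
    if len(table.algorithms) > 1:
        ref = reference or table.algorithms[0]
        rows = []
        for f in table.functions:
            row = {}
            for a in table.algorithms:
                if a == ref:
                    continue
                p, label = wilcoxon_signed_rank(
                    table.results[(ref, f)], table.results[(a, f)]
                )
                row[f"{a}_p"] = p
                row[f"{a}_label"] = label
            rows.append(pd.Series(row, name=f))
        out["wilcoxon"] = pd.DataFrame(rows)
        arv = friedman_average_ranks(avg).sort_values()
        out["arv"] = arv.to_frame()
        out["arv"]["rank"] = np.arange(1, arv.size + 1)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, df in out.items():
            df.to_csv(out_dir / f"{key}.csv")
        lines = ["# Benchmark report", "", "## Avg (best in *italics*)", ""]
        lines.append("| Function | " + " | ".join(table.algorithms) + " |")
        lines.append("|" + "---|" * (len(table.algorithms) + 1))
        for f in table.functions:
            cells = []
            for a in table.algorithms:
                s = f"{avg.loc[f, a]:.2E}"
                cells.append(f"*{s}*" if best.loc[f] == a else s)
            lines.append(f"| {f} | " + " | ".join(cells) + " |")
        if "arv" in out:
            lines += ["", "## Friedman average rank values", ""]
            lines.append("| Algorithm | ARV | Rank |")
            lines.append("|---|---|---|")
            for a, row in out["arv"].iterrows():
                lines.append(f"| {a} | {row['ARV']:.4f} | {int(row['rank'])} |")
        (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    return out
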