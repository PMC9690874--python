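"""All-vs-all benchmarking of the heuristic against the exact aligners.

For every unordered pair of a dataset both the heuristic (scoreH) and the
optimal (scoreO) alignment scores are computed.  Three quality metrics
summarise a run:

* **standard deviation** — sqrt(mean((scoreH - scoreO)^2)) over the pairs
  where the heuristic was *utilized* (anchored at least one stored
  subalignment); a root-mean-square score error, 0 meaning every utilized
  pair was aligned optimally;
* **utilization rate** — the percentage of pairs with at least one anchor;
* **exact match rate** — the percentage of utilized pairs whose heuristic
  score equals the optimum (reported over all pairs as well, where
  non-utilized pairs count as exact because the fallback *is* the exact
  aligner).

Because sample selection is random, a benchmark is repeated several times
with fresh samples and the reports averaged.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from itertools import combinations
from random import Random
from typing import Callable, Sequence as TSequence

import pandas as pd

from .errors import ParameterError
from .heuristic import LookupIndex, heuristic_align
from .pairwise import exact_align
from .store import LookupConfig, MemoryBackend, Sequence, SubalignmentStore

__all__ = [
    "PairEvaluation",
    "MetricsReport",
    "compute_metrics",
    "evaluate_all_pairs",
    "mean_report",
    "reports_frame",
]


@dataclass(frozen=True)
class PairEvaluation:
    """Heuristic vs optimal outcome for one sequence pair."""

    id_a: str
    id_b: str
    score_h: int
    score_o: int
    utilized: bool
    n_anchors: int = 0

    def __post_init__(self) -> None:
        if self.score_h > self.score_o:
            raise ParameterError("heuristic score cannot exceed the optimum")

    @property
    def exact(self) -> bool:
        return self.score_h == self.score_o


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate quality metrics for one benchmark repeat.

    ``sd`` and ``exact_match_rate`` are None when no pair was utilized
    (they are undefined over an empty set).  Rates are percentages.
    Timings are informational only.
    """

    n_pairs: int
    n_utilized: int
    sd: float | None
    utilization_rate: float
    exact_match_rate: float | None
    exact_match_rate_all: float
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def compute_metrics(evals: TSequence[PairEvaluation], **extra) -> MetricsReport:
    """Aggregate per-pair evaluations into a metrics report."""
    n_pairs = len(evals)
    utilized = [e for e in evals if e.utilized]
    n_util = len(utilized)
    if n_util:
        sd = math.sqrt(
            sum((e.score_h - e.score_o) ** 2 for e in utilized) / n_util
        )
        exact_rate = 100.0 * sum(e.exact for e in utilized) / n_util
    else:
        sd = None
        exact_rate = None
    utilization = 100.0 * n_util / n_pairs if n_pairs else 0.0
    exact_all = (
        100.0 * sum(e.exact for e in evals) / n_pairs if n_pairs else 100.0
    )
    return MetricsReport(
        n_pairs=n_pairs,
        n_utilized=n_util,
        sd=sd,
        utilization_rate=utilization,
        exact_match_rate=exact_rate,
        exact_match_rate_all=exact_all,
        **extra,
    )


def evaluate_all_pairs(
    dataset: TSequence[Sequence],
    config: LookupConfig,
    repeats: int = 1,
    seed: int = 0,
    backend_factory: Callable = MemoryBackend,
    return_pair_evals: bool = False,
):
    """Benchmark the heuristic on every unordered pair of ``dataset``.

    Each repeat draws a fresh sample (seeded deterministically from
    ``seed``), rebuilds the lookup table, and aligns all n*(n-1)/2 pairs
    both heuristically and exactly.  Returns a list of
    :class:`MetricsReport` (optionally paired with the per-pair records).
    """
    if len(dataset) < 2:
        raise ParameterError("dataset must contain at least 2 sequences")
    master = Random(seed)
    reports: list[MetricsReport] = []
    all_evals: list[list[PairEvaluation]] = []
    for rep in range(repeats):
        rep_seed = master.getrandbits(31)
        store = SubalignmentStore(backend_factory())
        store.load_sequences(dataset)
        t0 = time.perf_counter()
        store.draw_sample(config.z, rep_seed)
        build = store.build_lookup(config)
        t_build = time.perf_counter() - t0
        index = LookupIndex.from_store(store)
        occ_cache = {s.id: index.find_occurrences(s.seq) for s in dataset}
        evals: list[PairEvaluation] = []
        t_h = t_o = 0.0
        for sa, sb in combinations(dataset, 2):
            t0 = time.perf_counter()
            res = heuristic_align(
                sa.seq,
                sb.seq,
                store,
                config.scheme,
                index=index,
                hits_a=occ_cache[sa.id],
                hits_b=occ_cache[sb.id],
            )
            t_h += time.perf_counter() - t0
            t0 = time.perf_counter()
            opt = exact_align(sa.seq, sb.seq, config.scheme)
            t_o += time.perf_counter() - t0
            evals.append(
                PairEvaluation(
                    sa.id, sb.id, res.alignment.score, opt.score,
                    res.utilized, res.n_anchors,
                )
            )
        n_pairs = len(evals)
        report = compute_metrics(
            evals,
            timings={
                "preprocess_s": t_build,
                "heuristic_mean_s": t_h / n_pairs,
                "optimal_mean_s": t_o / n_pairs,
            },
            config={
                "k": config.k,
                "z": config.z,
                "threshold": config.resolved_threshold,
                "scheme": type(config.scheme).__name__,
                "repeat": rep,
                "seed": rep_seed,
                "n_lookup_rows": build.n_lookup_rows,
                "n_subseq_rows": build.n_subseq_rows,
            },
        )
        reports.append(report)
        all_evals.append(evals)
    if return_pair_evals:
        return reports, all_evals
    return reports


def mean_report(reports: TSequence[MetricsReport]) -> MetricsReport:
    """Average metrics across repeats (None-valued metrics are averaged
    over the repeats where they are defined)."""

    def _mean(values):
        values = [v for v in values if v is not None]
        return sum(values) / len(values) if values else None

    return MetricsReport(
        n_pairs=reports[0].n_pairs,
        n_utilized=round(sum(r.n_utilized for r in reports) / len(reports)),
        sd=_mean([r.sd for r in reports]),
        utilization_rate=_mean([r.utilization_rate for r in reports]),
        exact_match_rate=_mean([r.exact_match_rate for r in reports]),
        exact_match_rate_all=_mean([r.exact_match_rate_all for r in reports]),
        timings={
            key: _mean([r.timings.get(key) for r in reports])
            for key in (reports[0].timings or {})
        },
        config={**reports[0].config, "repeats": len(reports)},
    )


def reports_frame(reports: TSequence[MetricsReport]) -> pd.DataFrame:
    """Tabulate reports (one row per repeat) for TSV export."""
    rows = []
    for r in reports:
        rows.append(
            {
                "k": r.config.get("k"),
                "z": r.config.get("z"),
                "scheme": r.config.get("scheme"),
                "repeat": r.config.get("repeat"),
                "n_pairs": r.n_pairs,
                "n_utilized": r.n_utilized,
                "sd": r.sd,
                "utilization_pct": r.utilization_rate,
                "exact_match_pct": r.exact_match_rate,
                "exact_match_all_pct": r.exact_match_rate_all,
                "preprocess_s": r.timings.get("preprocess_s"),
                "heuristic_mean_s": r.timings.get("heuristic_mean_s"),
                "optimal_mean_s": r.timings.get("optimal_mean_s"),
            }
        )
    return pd.DataFrame(rows)
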