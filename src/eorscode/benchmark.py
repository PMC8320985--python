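"""Benchmark harness sweeping (n, d) cells with one or more methods."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ConstraintProfile, coding_rate
from .eo import EOParams
from .oracle import build_conflict_graph, greedy_random_baseline, max_clique_exact
from .rs import RSParams
from .search import eors_search

__all__ = ["BenchmarkRow", "benchmark_sweep", "rows_to_tsv", "rows_to_json"]

METHODS = ("eors", "greedy", "exact")


@dataclass
class BenchmarkRow:
    n: int
    d: int
    method: str
    size: int | None
    seed: int | None
    budget: str
    error: str | None = None

    @property
    def rate(self) -> float | None:
        # always recomputed from size and n, never stored
        if self.size is None or self.size < 1:
            return None
        return coding_rate(self.size, self.n)


def _run_cell(
    n: int,
    d: int,
    method: str,
    seed: int | None,
    eo_params: EOParams,
    rs_params: RSParams,
    restarts: int,
) -> BenchmarkRow:
    profile = ConstraintProfile(n=n, d=d)
    if method == "eors":
        res = eors_search(profile, eo_params, rs_params, seed=seed)
        budget = f"eo:{eo_params.t_max}x{eo_params.pop_size},rs:{rs_params.budget}"
        return BenchmarkRow(n, d, method, len(res.final_set), seed, budget)
    if method == "greedy":
        code = greedy_random_baseline(profile, restarts=restarts, seed=seed)
        return BenchmarkRow(n, d, method, len(code), seed, f"restarts:{restarts}")
    if method == "exact":
        code = max_clique_exact(build_conflict_graph(profile))
        return BenchmarkRow(n, d, method, len(code), seed, "exact")
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def benchmark_sweep(
    cells: Iterable[tuple[int, int]],
    methods: Sequence[str] = ("eors", "greedy"),
    seed: int | None = None,
    eo_params: EOParams | None = None,
    rs_params: RSParams | None = None,
    restarts: int = 10,
) -> list[BenchmarkRow]:
    """One row per (n, d, method); per-cell failures are recorded, not raised."""
    eo_params = eo_params or EOParams()
    rs_params = rs_params or RSParams()
    rows = []
    for n, d in cells:
        for method in methods:
            try:
                rows.append(
                    _run_cell(n, d, method, seed, eo_params, rs_params, restarts)
                )
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                rows.append(BenchmarkRow(n, d, method, None, seed, "", str(exc)))
    return rows


def rows_to_tsv(rows: Sequence[BenchmarkRow]) -> str:
    lines = ["n\td\tmethod\tsize\trate\tseed\tbudget\terror"]
    for r in rows:
        rate = f"{r.rate:.6f}" if r.rate is not None else ""
        lines.append(
            f"{r.n}\t{r.d}\t{r.method}\t{r.size if r.size is not None else ''}"
            f"\t{rate}\t{r.seed if r.seed is not None else ''}\t{r.budget}"
            f"\t{r.error or ''}"
        )
    return "\n".join(lines) + "\n"


def rows_to_json(rows: Sequence[BenchmarkRow]) -> str:
    payload = [
        {
            "n": r.n,
            "d": r.d,
            "method": r.method,
            "size": r.size,
            "rate": r.rate,
            "seed": r.seed,
            "budget": r.budget,
            "error": r.error,
        }
        for r in rows
    ]
    return json.dumps(payload, indent=2)
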