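"""Shuffle-and-repeat benchmarking of the clique solvers.

Protocol: each (graph, algorithm) pair is solved ``repeats`` times, each
repeat on a freshly relabeled copy of the graph (structure preserved,
vertex numbers shuffled), and the mean and sample SD of the wall-clock
times are recorded together with the optimum and an all-runs-agree flag.
Speedup of algorithm A over reference B is mean_time(B) / mean_time(A).

Timing numbers are hardware-dependent and are reported, never asserted.
"""

from __future__ import annotations

import csv
import io
import statistics
import time
from dataclasses import dataclass, asdict, fields
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

from .graph import WeightedGraph
from .search import DEFAULT_TLIMIT, solve
from .synthetic import shuffle_vertices

CSV_HEADER = [
    "instance", "n", "density", "algorithm", "repeats",
    "mean_s", "sd_s", "weight", "agree",
]


@dataclass(frozen=True)
class BenchRecord:
    """One benchmark row: an (instance, algorithm) pair."""

    instance: str
    n: int
    density: float
    algorithm: str
    repeats: int
    mean_s: float
    sd_s: float
    weight: int
    agree: bool


def _density(G: WeightedGraph) -> float:
    pairs = G.n * (G.n - 1) // 2
    return G.num_edges / pairs if pairs else 0.0


def run_benchmark(
    graphs: Sequence[tuple[str, WeightedGraph]],
    algorithms: Sequence[str] = ("static", "dynamic"),
    repeats: int = 100,
    shuffle: bool = True,
    seed: int = 0,
    tlimit: float = DEFAULT_TLIMIT,
    time_cap: Optional[float] = None,
) -> list[BenchRecord]:
    """Run every algorithm on every graph with per-repeat vertex shuffling.

    ``time_cap``, when set, clips each reported per-run time from below at
    ``time_cap[0]`` and above at ``time_cap[1]`` (cosmetic reporting parity
    with capped published tables); raw times are used otherwise.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    if not graphs or not algorithms:
        raise ValueError("need at least one graph and one algorithm")
    records: list[BenchRecord] = []
    for g_idx, (name, G) in enumerate(graphs):
        for algorithm in algorithms:
            times: list[float] = []
            optima: list[int] = []
            for r in range(repeats):
                inst = (
                    shuffle_vertices(G, seed=seed + 100_003 * g_idx + r)
                    if shuffle
                    else G
                )
                t0 = time.perf_counter()
                result = solve(inst, variant=algorithm, tlimit=tlimit)
                dt = time.perf_counter() - t0
                if time_cap is not None:
                    lo, hi = time_cap
                    dt = min(max(dt, lo), hi)
                times.append(dt)
                optima.append(result.weight)
            records.append(
                BenchRecord(
                    instance=name,
                    n=G.n,
                    density=round(_density(G), 6),
                    algorithm=algorithm,
                    repeats=repeats,
                    mean_s=statistics.fmean(times),
                    sd_s=statistics.stdev(times) if repeats > 1 else 0.0,
                    weight=optima[0],
                    agree=len(set(optima)) == 1,
                )
            )
    return records


def speedup_table(
    records: Iterable[BenchRecord], reference: str
) -> pd.DataFrame:
    """Per-instance speedups: mean time of ``reference`` over each algorithm."""
    df = records_to_dataframe(records)
    ref = df[df.algorithm == reference].set_index("instance").mean_s
    out = df[df.algorithm != reference].copy()
    out["speedup"] = out.instance.map(ref) / out.mean_s
    return out[["instance", "algorithm", "mean_s", "speedup"]]


def records_to_dataframe(records: Iterable[BenchRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=CSV_HEADER)


def write_csv(records: Iterable[BenchRecord], stream: TextIO) -> None:
    writer = csv.writer(stream)
    writer.writerow(CSV_HEADER)
    for r in records:
        writer.writerow([getattr(r, f) for f in CSV_HEADER])


def read_csv(source: Union[str, TextIO]) -> list[BenchRecord]:
    """Parse benchmark CSV back into records (round-trips ``write_csv``)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    reader = csv.DictReader(source)
    out = []
    for row in reader:
        kwargs = {}
        for f in fields(BenchRecord):
            raw = row[f.name]
            if f.type == "bool":
                kwargs[f.name] = raw in ("True", "true", "1")
            elif f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        out.append(BenchRecord(**kwargs))
    return out
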