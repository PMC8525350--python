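"""End-to-end runs: simulate -> prep -> call -> summarize, reproducibly.

One global seed fans out deterministically to per-stage child seeds (via
numpy SeedSequence), so an identical config always yields byte-identical
outputs and individual stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io
from .calling import CallResult, Scoring, call_reads
from .enzymes import ENZYMES
from .prep import PrepResult, prep_reads
from .simulate import (
    AmpliconTarget, SimScenario, make_amplicon, simulate_run,
)
from .summary import OutcomeTable, summarize

__all__ = ["RunConfig", "RunResult", "run_pipeline", "child_seeds"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from one global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    The filter constants default to the analyzer's published settings: a
    maximum per-base error probability of 0.05, events more than 5 bp from
    either primer annealing site, and event signatures seen at least twice.
    """

    scenario: SimScenario = field(default_factory=SimScenario)
    amplicon_length: int = 283
    enzyme: str = "NcoI"
    primer_len: int = 20
    min_overlap: int = 10
    max_mismatch_frac: float = 0.25
    max_err_prob: float = 0.05
    primer_kmer: int = 10
    primer_window: int = 30
    margin: int = 5
    min_support: int = 2
    scoring: Scoring = field(default_factory=Scoring)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["del_size_dist"] = {
            int(k): float(v) for k, v in self.scenario.del_size_dist.items()
        }
        d["scenario"]["ins_size_dist"] = {
            int(k): float(v) for k, v in self.scenario.ins_size_dist.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scenario" in d and isinstance(d["scenario"], dict):
            d["scenario"] = SimScenario(**d["scenario"])
        if "scoring" in d and isinstance(d["scoring"], dict):
            d["scoring"] = Scoring(**d["scoring"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    outdir: Path
    target: AmpliconTarget
    prep: PrepResult
    call: CallResult
    table: OutcomeTable


def _confusion(truth: dict, calls, dropped: dict[str, str]) -> pd.DataFrame:
    rows = []
    called_by_id = {c.pair_id: c.klass for c in calls}
    for pair_id, t in truth.items():
        called = called_by_id.get(pair_id, f"dropped:{dropped.get(pair_id, '?')}")
        rows.append(dict(truth=t.klass, called=called))
    df = pd.DataFrame(rows)
    return pd.crosstab(df["truth"], df["called"])


def run_pipeline(config: RunConfig, outdir) -> RunResult:
    """Execute all stages in order and write every artifact into ``outdir``.

    Writes the mate FASTQs and truth TSV, merged-read FASTQ and prep stats,
    events and per-read calls TSVs, the outcome-table JSON, a truth-vs-called
    confusion table, and a serialized copy of the resolved config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {config.enzyme!r} "
                         f"(available: {sorted(ENZYMES)})")
    amp_seed, sim_seed = child_seeds(config.seed, 2)

    # stage: target + simulation
    target = make_amplicon(
        config.amplicon_length, ENZYMES[config.enzyme],
        primer_len=config.primer_len, seed=amp_seed,
    )
    io.write_target(target, outdir / "amplicon.fasta", outdir / "amplicon.yaml")
    rng = np.random.default_rng(sim_seed)
    pairs = simulate_run(target, config.scenario, rng)
    io.write_run(pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq",
                 outdir / "truth.tsv")

    # stage: merge + filters
    prep = prep_reads(
        pairs, target,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        max_err_prob=config.max_err_prob,
        primer_kmer=config.primer_kmer,
        primer_window=config.primer_window,
    )
    io.write_merged_reads(prep.reads, outdir / "merged.fastq")
    io.write_prep_stats(prep.stats, outdir / "prep_stats.tsv")

    # stage: event calling
    call = call_reads(
        prep.reads, target, scoring=config.scoring,
        margin=config.margin, min_support=config.min_support,
    )
    io.write_events(call.events, outdir / "events.tsv")
    io.write_calls(call.calls, outdir / "calls.tsv")

    # stage: summary
    table = summarize(call.calls)
    io.dump_json(table.to_dict(), outdir / "outcome_table.json")

    truth = {p.pair_id: p.truth for p in pairs if p.truth is not None}
    if truth:
        _confusion(truth, call.calls, prep.dropped).to_csv(
            outdir / "confusion.tsv", sep="\t"
        )
    config.to_yaml(outdir / "config_resolved.yaml")
    return RunResult(outdir=outdir, target=target, prep=prep, call=call,
                     table=table)
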