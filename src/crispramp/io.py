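"""File formats: FASTQ mate pairs, truth tables, amplicon annotations,
scenario configs, and the tabular outputs of each pipeline stage.

Sequence files go through Bio.SeqIO (Phred+33 FASTQ, FASTA); annotations and
scenario configs are YAML; tables are tab-separated and read back with
pandas.  Intervals are serialized 0-based half-open, matching the in-memory
convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CalledEvent, ReadCall
from .enzymes import ENZYMES, EnzymeSite
from .prep import MergedRead, PrepStats
from .simulate import WT, AmpliconTarget, EditOutcome, ReadPair, SimScenario

__all__ = [
    "write_run", "read_fastq_pairs", "read_truth",
    "write_target", "read_target", "scenario_to_yaml", "scenario_from_yaml",
    "write_merged_reads", "write_prep_stats", "write_events", "write_calls",
    "read_band_tsv", "read_counts_tsv",
]


def _pair_records(pairs: Iterable[ReadPair], mate: int):
    for p in pairs:
        seq = p.r1_seq if mate == 1 else p.r2_seq
        qual = p.r1_qual if mate == 1 else p.r2_qual
        rec = SeqRecord(Seq(seq), id=f"{p.pair_id}/{mate}", description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in qual]
        yield rec


def write_run(
    pairs: list[ReadPair], r1_path, r2_path, truth_path=None
) -> None:
    """Write mates to two Phred+33 FASTQ files and, if requested, the truth
    table (pair_id, klass, ref_start, ref_end, ins_seq) as TSV."""
    SeqIO.write(_pair_records(pairs, 1), str(r1_path), "fastq")
    SeqIO.write(_pair_records(pairs, 2), str(r2_path), "fastq")
    if truth_path is not None:
        rows = []
        for p in pairs:
            t = p.truth if p.truth is not None else EditOutcome(WT)
            rows.append(
                dict(pair_id=p.pair_id, klass=t.klass, ref_start=t.ref_start,
                     ref_end=t.ref_end, ins_seq=t.ins_seq)
            )
        pd.DataFrame(
            rows, columns=["pair_id", "klass", "ref_start", "ref_end", "ins_seq"]
        ).to_csv(truth_path, sep="\t", index=False)


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Read two FASTQ files back into mate pairs (names must end /1 and /2
    and come in the same order)."""
    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    ):
        id1, id2 = rec1.id.rsplit("/", 1)[0], rec2.id.rsplit("/", 1)[0]
        if id1 != id2:
            raise ValueError(f"unpaired reads: {rec1.id} vs {rec2.id}")
        pairs.append(
            ReadPair(
                pair_id=id1,
                r1_seq=str(rec1.seq),
                r2_seq=str(rec2.seq),
                r1_qual=np.array(rec1.letter_annotations["phred_quality"]),
                r2_qual=np.array(rec2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def read_truth(truth_path) -> dict[str, EditOutcome]:
    df = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.pair_id)] = EditOutcome(
            row.klass, int(row.ref_start), int(row.ref_end), str(row.ins_seq)
        )
    return out


def write_target(target: AmpliconTarget, fasta_path, ann_path) -> None:
    """Amplicon reference as FASTA plus a YAML sidecar with the interval
    annotations (0-based half-open)."""
    SeqIO.write(
        [SeqRecord(Seq(target.ref_seq), id=target.name, description="")],
        str(fasta_path),
        "fasta",
    )
    ann = {
        "name": target.name,
        "fwd_primer": list(target.fwd_primer),
        "rev_primer": list(target.rev_primer),
        "protospacer": list(target.protospacer),
        "pam": list(target.pam),
        "cut_pos": target.cut_pos,
        "enzyme_sites": [
            {"enzyme": enz.name, "pattern": enz.pattern,
             "cut_offset": enz.cut_offset, "interval": [s, e]}
            for enz, (s, e) in target.enzyme_sites
        ],
    }
    Path(ann_path).write_text(yaml.safe_dump(ann, sort_keys=False))


def read_target(fasta_path, ann_path) -> AmpliconTarget:
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    ann = yaml.safe_load(Path(ann_path).read_text())
    sites = []
    for s in ann.get("enzyme_sites", []):
        enz = ENZYMES.get(s["enzyme"]) or EnzymeSite(
            s["enzyme"], s["pattern"], s["cut_offset"]
        )
        sites.append((enz, tuple(s["interval"])))
    return AmpliconTarget(
        name=ann["name"],
        ref_seq=str(rec.seq),
        fwd_primer=tuple(ann["fwd_primer"]),
        rev_primer=tuple(ann["rev_primer"]),
        protospacer=tuple(ann["protospacer"]),
        pam=tuple(ann["pam"]),
        cut_pos=int(ann["cut_pos"]),
        enzyme_sites=tuple(sites),
    )


def scenario_to_yaml(scenario: SimScenario, path) -> None:
    d = {
        "edited_fraction": scenario.edited_fraction,
        "class_weights": dict(scenario.class_weights),
        "del_size_dist": {int(k): float(v) for k, v in scenario.del_size_dist.items()},
        "ins_size_dist": {int(k): float(v) for k, v in scenario.ins_size_dist.items()},
        "ins1bp_base_bias": dict(scenario.ins1bp_base_bias),
        "read_len": scenario.read_len,
        "n_pairs": scenario.n_pairs,
        "mean_q": scenario.mean_q,
        "qual_sd": scenario.qual_sd,
        "substitution_errors": scenario.substitution_errors,
        "seed": scenario.seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def scenario_from_yaml(path) -> SimScenario:
    d = yaml.safe_load(Path(path).read_text())
    return SimScenario(**d)


def _prob_to_phred(p: np.ndarray) -> list[int]:
    q = np.rint(-10.0 * np.log10(np.clip(p, 1e-9, 1.0))).astype(int)
    return [int(x) for x in np.clip(q, 0, 90)]


def write_merged_reads(reads: list[MergedRead], path) -> None:
    """Merged consensus reads as FASTQ, error probabilities re-encoded as
    Phred scores (rounded)."""
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.pair_id, description="")
        rec.letter_annotations["phred_quality"] = _prob_to_phred(r.err_prob)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_prep_stats(stats: PrepStats, path) -> None:
    pd.DataFrame([stats.as_dict()]).to_csv(path, sep="\t", index=False)


def write_events(events: list[CalledEvent], path) -> None:
    """Called event signatures with support; 1-based inclusive display
    coordinates are carried alongside the 0-based half-open ones."""
    rows = [
        dict(klass=e.klass, ref_start=e.ref_start, ref_end=e.ref_end,
             ins_seq=e.ins_seq, support=e.support,
             display_start=e.ref_start + 1, display_end=e.ref_end)
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["klass", "ref_start", "ref_end", "ins_seq", "support",
                       "display_start", "display_end"]
    ).to_csv(path, sep="\t", index=False)


def write_calls(calls: list[ReadCall], path) -> None:
    rows = [
        dict(pair_id=c.pair_id, klass=c.klass,
             n_events=len(c.events), multi_event=c.multi_event,
             events=";".join(
                 f"{e.klass}:{e.ref_start}-{e.ref_end}:{e.ins_seq}"
                 for e in c.events
             ))
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["pair_id", "klass", "n_events", "multi_event", "events"]
    ).to_csv(path, sep="\t", index=False)


def read_band_tsv(path) -> pd.DataFrame:
    """Band intensities: columns lane, band ('intact' or 'cleaved'),
    intensity."""
    df = pd.read_csv(path, sep="\t")
    required = {"lane", "band", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"band TSV needs columns {sorted(required)}")
    return df


def read_counts_tsv(path) -> pd.DataFrame:
    """Colony counts: columns replicate, plate_type ('resistant' or
    'total'), colonies, dilution_factor, plated_volume_ml."""
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "plate_type", "colonies", "dilution_factor",
                "plated_volume_ml"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV needs columns {sorted(required)}")
    return df


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
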