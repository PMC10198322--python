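"""Sliding-window deployment of the Qs score over FASTA input.

Coordinates are 0-based half-open in memory and in BED output; the
human-readable TSV uses 1-based inclusive coordinates and says so in its
header.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

from .classify import MotifCall, classify
from .projection import ProjectionModel, ScoreProfile, SequenceRecord, normalize_sequence

__all__ = [
    "ScanConfig",
    "scan_sequence",
    "call_intervals",
    "read_fasta",
    "write_bed",
    "write_calls_tsv",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scanner settings.

    ``window_size`` 25 nt spans the shortest motif-forming repeats
    ((GT)_8 = 16 nt) with margin; ``report_threshold`` 1.2 is the G4
    formation threshold on |Qs|.  Final partial windows are skipped by
    default because the (n-1)/n factor biases short windows low; set
    ``score_partial`` to score them anyway.
    """

    psi_degrees: float = 30.0
    window_size: int = 25
    step: int = 1
    report_threshold: float = 1.2
    merge_adjacent: bool = True
    score_partial: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.report_threshold < 0:
            raise ValueError("report_threshold must be >= 0")


def scan_sequence(rec: SequenceRecord, cfg: ScanConfig | None = None) -> ScoreProfile:
    """Score every window of ``rec`` under ``cfg``.

    Windows sit at 0-based half-open ``[start, start + window)``; a record
    shorter than the window yields a single whole-sequence window; an empty
    record yields an empty profile.
    """
    cfg = cfg or ScanConfig()
    model = ProjectionModel(cfg.psi_degrees)
    n = rec.n
    windows: list[tuple[int, int, float]] = []
    if n == 0:
        return ScoreProfile(rec.id, cfg.psi_degrees, cfg.window_size, cfg.step, ())
    h = model.heights(rec.seq)
    if n < cfg.window_size:
        qs = 0.0 if n <= 1 else float(0.5 * (h[:-1] + h[1:]).sum() / n)
        windows.append((0, n, qs))
        return ScoreProfile(
            rec.id, cfg.psi_degrees, cfg.window_size, cfg.step, tuple(windows)
        )
    traps = 0.5 * (h[:-1] + h[1:])
    csum = np.concatenate(([0.0], np.cumsum(traps)))
    w = cfg.window_size
    starts = np.arange(0, n - w + 1, cfg.step)
    scores = (csum[starts + w - 1] - csum[starts]) / w
    windows.extend(
        (int(s), int(s) + w, float(q)) for s, q in zip(starts, scores)
    )
    if cfg.score_partial:
        last_full = int(starts[-1])
        for s in range(last_full + cfg.step, n - 1, cfg.step):
            length = n - s
            qs = float((csum[n - 1] - csum[s]) / length)
            windows.append((s, n, qs))
    return ScoreProfile(rec.id, cfg.psi_degrees, cfg.window_size, cfg.step, tuple(windows))


def call_intervals(profile: ScoreProfile, cfg: ScanConfig | None = None) -> list[MotifCall]:
    """Threshold a profile into strand-resolved candidate intervals.

    Windows with ``Qs >= threshold`` become plus-strand calls; windows with
    ``Qs <= -threshold`` become minus-strand calls (by complement
    antisymmetry a strongly negative plus-strand window marks a G-rich
    minus strand, i.e. an i-motif candidate on the plus strand).  With
    ``merge_adjacent``, overlapping or touching same-strand calls merge to
    maximal intervals retaining the extremal window score.
    """
    cfg = cfg or ScanConfig()
    thr = cfg.report_threshold
    raw: dict[str, list[tuple[int, int, float]]] = {"+": [], "-": []}
    for start, end, qs in profile.windows:
        if qs >= thr:
            raw["+"].append((start, end, qs))
        elif qs <= -thr:
            raw["-"].append((start, end, qs))
    calls: list[MotifCall] = []
    for strand, items in raw.items():
        if not items:
            continue
        if not cfg.merge_adjacent:
            calls.extend(
                MotifCall(profile.record_id, s, e, strand, q, classify(q))
                for s, e, q in items
            )
            continue
        cur_s, cur_e, cur_q = items[0]
        for s, e, q in items[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
                if abs(q) > abs(cur_q):
                    cur_q = q
            else:
                calls.append(
                    MotifCall(profile.record_id, cur_s, cur_e, strand, cur_q, classify(cur_q))
                )
                cur_s, cur_e, cur_q = s, e, q
        calls.append(
            MotifCall(profile.record_id, cur_s, cur_e, strand, cur_q, classify(cur_q))
        )
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield normalized records from a (optionally gzipped) FASTA file."""
    path = Path(path)
    if path.suffix == ".gz":
        handle: TextIO = gzip.open(path, "rt")
    else:
        handle = open(path)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            yield normalize_sequence(str(rec.seq), id=rec.id)
    finally:
        handle.close()


def _bed_score(qs: float) -> int:
    return round(1000 * min(abs(qs) / 3.0, 1.0))


def write_bed(calls: Iterable[MotifCall], handle: TextIO) -> None:
    """BED6: chrom, start, end, name=label, score=1000*min(|Qs|/3, 1), strand."""
    for c in calls:
        handle.write(
            f"{c.record_id}\t{c.start}\t{c.end}\t{c.label}\t{_bed_score(c.qs)}\t{c.strand}\n"
        )


def write_calls_tsv(calls: Iterable[MotifCall], handle: TextIO) -> None:
    """Human-readable call table; coordinates 1-based inclusive."""
    handle.write("# coordinates: 1-based inclusive\n")
    handle.write("record_id\tstart\tend\tstrand\tqs\tlabel\tsource\tcore_start\tcore_end\n")
    for c in calls:
        cs = "" if c.core_start is None else str(c.core_start + 1)
        ce = "" if c.core_end is None else str(c.core_end)
        handle.write(
            f"{c.record_id}\t{c.start + 1}\t{c.end}\t{c.strand}\t{c.qs:.6g}\t"
            f"{c.label}\t{c.source}\t{cs}\t{ce}\n"
        )
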