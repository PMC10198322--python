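"""Score-band classification and dinucleotide repeat tract detection.

Band semantics (defined for Qs computed at psi = 30 degrees, amplitude 3):

==================  =========================  =====================================
label               Qs band                    reading
==================  =========================  =====================================
``ZG4_prone``       Qs > 2                     very high score; alternating-purine/
                                               pyrimidine repeats that adopt
                                               left-handed G4 under crowding
``G4_candidate``    1.2 < Qs <= 2              above the G4 formation threshold
``tetrahelix_band``  0.7 <= Qs <= 1.2          just below the G4 threshold; the
                                               band of non-G4 tetrahelical formers
                                               ((GA)n-type, AGAG-quartet motifs)
``imotif_candidate`` Qs < -1.2                 mirror of the G4 threshold: C-rich
                                               plus strand / G-rich minus strand
``none``            otherwise                  e.g. a bare (GA)_6 at 0.6875
==================  =========================  =====================================

The tetrahelix band is nominally quoted as 0.7-1.1 at print precision, but
its defining member (the 31-nt VK motif) scores 1.1129 under the model, so
the band's true upper edge is the G4 threshold itself: everything from 0.7
up to and including 1.2 that is not above the threshold is in the band.
The lower edge 0.7 is sharp — a 6-unit GA repeat (0.6875) stays unfolded
and falls outside.  The i-motif edge at -1.2 follows from the exact
antisymmetry of the score under complementation, which makes the mirrored
G4 threshold the only non-arbitrary choice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .projection import ProjectionModel, SequenceRecord, complement, qs_score

__all__ = [
    "LABELS",
    "MotifCall",
    "RepeatTract",
    "classify",
    "find_dinucleotide_repeats",
    "refine_call",
    "tract_calls",
    "annotate_sequence",
]

LABELS = ("ZG4_prone", "G4_candidate", "tetrahelix_band", "imotif_candidate", "none")

#: Critical repeat range for Z-G4 / tetrahelical motif adoption: six repeats
#: is the detection default, eight the "confident" tier.
MIN_REPEATS_DEFAULT = 6
MIN_REPEATS_CONFIDENT = 8

#: Shortest repeat validated to cross the Z-G4 band: a 6-unit GT tract, 12 nt.
MIN_CORE_LEN = 12


def classify(qs_at_psi30: float) -> str:
    """Map a Qs score (psi = 30 convention) to its structural class label."""
    q = qs_at_psi30
    if q > 2.0:
        return "ZG4_prone"
    if q > 1.2:
        return "G4_candidate"
    if 0.7 <= q <= 1.2:
        return "tetrahelix_band"
    if q < -1.2:
        return "imotif_candidate"
    return "none"


@dataclass(frozen=True)
class MotifCall:
    """A classified candidate interval on one strand.

    Coordinates are 0-based half-open on the plus strand of the scanned
    record.  ``qs`` is the score the label was assigned from: the extremal
    window score for raw scanner calls, or the core/tract score after
    refinement (``core_start``/``core_end`` then delimit the scored core).
    ``source`` records which route produced the call (``scan``, ``tract``).
    """

    record_id: str
    start: int
    end: int
    strand: str
    qs: float
    label: str
    source: str = "scan"
    core_start: int | None = None
    core_end: int | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class RepeatTract:
    """A maximal dinucleotide repeat run.

    ``unit`` is phase-normalized (a GT-alternation starting at T is still
    unit GT); ``count`` is the number of full units, so ``end - start ==
    2 * count``; a dangling half unit is flagged by ``half_unit`` and sits
    at ``end`` (strand ``+``) without extending the tract coordinates.
    Minus-strand tracts are alternations of the complementary bases on the
    plus strand (a CA run is a GT tract on the minus strand).
    """

    unit: str
    start: int
    end: int
    count: int
    strand: str = "+"
    half_unit: bool = False

    @property
    def span(self) -> int:
        """Full run length in nt, trailing half unit included."""
        return self.end - self.start + (1 if self.half_unit else 0)


def _alternating_runs(seq: str, a: str, b: str):
    """Yield (start, end) of maximal runs alternating strictly between a and b."""
    pattern = re.compile(f"{a}(?:{b}{a})*{b}?|{b}(?:{a}{b})*{a}?")
    for m in pattern.finditer(seq):
        if m.end() - m.start() >= 2:
            yield m.start(), m.end()


def find_dinucleotide_repeats(
    rec: SequenceRecord | str,
    min_repeats: int = MIN_REPEATS_DEFAULT,
    units: tuple[str, ...] = ("GT", "GA"),
    include_complements: bool = True,
) -> list[RepeatTract]:
    """Locate maximal dinucleotide repeat tracts, greedy left to right.

    For each unit both phases are matched (GT == TG by rotation).  With
    ``include_complements`` the complementary alternation is also searched
    and reported as the same unit on the minus strand.  Tracts with fewer
    than ``min_repeats`` full units are dropped.
    """
    seq = rec.seq if isinstance(rec, SequenceRecord) else rec
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    tracts: list[RepeatTract] = []
    seen_pairs: set[frozenset[str]] = set()
    for unit in units:
        unit = unit.upper()
        if len(unit) != 2 or unit[0] == unit[1] or not set(unit) <= set("ACGT"):
            raise ValueError(f"degenerate or invalid dinucleotide unit {unit!r}")
        searches = [(unit, "+")]
        comp_unit = complement(unit)
        if include_complements and frozenset(comp_unit) != frozenset(unit):
            searches.append((comp_unit, "-"))
        for target, strand in searches:
            pair = frozenset(target)
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            for run_start, run_end in _alternating_runs(seq, target[0], target[1]):
                length = run_end - run_start
                count = length // 2
                if count < min_repeats:
                    continue
                tracts.append(
                    RepeatTract(
                        unit=unit,
                        start=run_start,
                        end=run_start + 2 * count,
                        count=count,
                        strand=strand,
                        half_unit=bool(length % 2),
                    )
                )
    tracts.sort(key=lambda t: (t.start, t.end))
    return tracts


def _best_core(
    heights, start: int, end: int, sign: float, min_len: int
) -> tuple[int, int, float]:
    """Maximal mean-trapezoid subsegment of [start, end), length >= min_len.

    ``sign`` +1 maximizes Qs, -1 minimizes (minus-strand calls).  O(L^2) in
    the call length, which is short.  Returns (core_start, core_end, qs).
    """
    h = heights[start:end]
    L = len(h)
    min_len = min(min_len, L)
    traps = 0.5 * (h[:-1] + h[1:])
    csum = traps.cumsum()
    best = (start, end, sign * -1e30)
    for length in range(min_len, L + 1):
        for s in range(0, L - length + 1):
            area = csum[s + length - 2] - (csum[s - 1] if s > 0 else 0.0)
            qs = area / length
            if sign * qs > sign * best[2]:
                best = (start + s, start + s + length, float(qs))
    return best


def refine_call(
    rec: SequenceRecord,
    call: MotifCall,
    model: ProjectionModel | None = None,
    min_core_len: int = MIN_CORE_LEN,
) -> MotifCall:
    """Re-score a scanner call by its best-scoring core subsegment.

    Window scores dilute short motifs with flanking background: a 16-nt
    repeat tract inside a 25-nt window can never reach the Z-G4 band even
    though the tract itself scores above 2.  The core is the maximal
    mean-area subsegment of the call, at least ``min_core_len`` nt long;
    the call keeps its merged coordinates but takes its ``qs`` and label
    from the core.

    Note that core scores of length close to ``min_core_len`` sit on a
    different (wider) null distribution than full-window scores, so
    explicit refinement will promote some generically G-rich stretches
    into higher bands.  The default pipeline (:func:`annotate_sequence`)
    therefore labels scanner calls from their window scores and reserves
    above-window-resolution classification for exact repeat tracts.
    """
    model = model or ProjectionModel()
    heights = model.heights(rec.seq)
    sign = 1.0 if call.strand == "+" else -1.0
    cs, ce, qs = _best_core(heights, call.start, call.end, sign, min_core_len)
    return replace(call, qs=qs, label=classify(qs), core_start=cs, core_end=ce)


def tract_calls(
    rec: SequenceRecord,
    tracts: list[RepeatTract],
    model: ProjectionModel | None = None,
) -> list[MotifCall]:
    """Score repeat tracts directly and emit calls for classifiable ones.

    The tract is its own core: its Qs is computed over the full run (half
    unit included).  Tracts whose score falls in no band yield nothing —
    e.g. a bare 6-unit GA tract scores 0.69, just under the tetrahelix
    band, and is not called.
    """
    model = model or ProjectionModel()
    calls = []
    for t in tracts:
        stop = t.start + t.span
        qs = qs_score(rec.seq[t.start : stop], model)
        label = classify(qs)
        if label == "none":
            continue
        calls.append(
            MotifCall(
                record_id=rec.id,
                start=t.start,
                end=stop,
                strand="+" if qs >= 0 else "-",
                qs=qs,
                label=label,
                source="tract",
                core_start=t.start,
                core_end=stop,
            )
        )
    return calls


def annotate_sequence(
    rec: SequenceRecord,
    config=None,
    min_repeats: int = MIN_REPEATS_DEFAULT,
    units: tuple[str, ...] = ("GT", "GA"),
    min_core_len: int | None = None,
) -> list[MotifCall]:
    """Full classification pipeline for one record.

    Combines two complementary routes:

    * sliding-window scan -> interval calls, labelled from their extremal
      window score, which find any sufficiently G-rich (or C-rich)
      stretch; and
    * exact dinucleotide tract detection -> direct tract scoring, which
      recovers short repeat motifs a window dilutes below the Z-G4 band
      and the tetrahelix band (0.7-1.1) that sits below the scanner's 1.2
      cutoff.  The repeat route is what promotes a (GT)_8 tract inside a
      25-nt window to Z-G4-prone.

    Pass ``min_core_len`` to additionally re-score scanner calls by their
    best core subsegment (see :func:`refine_call` for the caveat on the
    null distribution of short cores).  Overlapping same-strand calls from
    the two routes are merged; the merged call keeps the score and label
    of the member with the larger |Qs|.
    """
    from .scanner import ScanConfig, call_intervals, scan_sequence

    cfg = config or ScanConfig()
    profile = scan_sequence(rec, cfg)
    model = ProjectionModel(cfg.psi_degrees)
    scan = call_intervals(profile, cfg)
    if min_core_len is not None:
        scan = [refine_call(rec, c, model, min_core_len) for c in scan]
    tr = tract_calls(rec, find_dinucleotide_repeats(rec, min_repeats, units), model)

    merged: list[MotifCall] = []
    for call in sorted(scan + tr, key=lambda c: (c.strand, c.start, c.end)):
        prev = merged[-1] if merged else None
        if prev is not None and prev.strand == call.strand and call.start <= prev.end:
            keep, other = (prev, call) if abs(prev.qs) >= abs(call.qs) else (call, prev)
            merged[-1] = replace(
                keep,
                start=min(prev.start, call.start),
                end=max(prev.end, call.end),
                source=keep.source if keep.source == other.source else "scan+tract",
            )
        else:
            merged.append(call)
    merged.sort(key=lambda c: (c.start, c.end, c.strand))
    return merged
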