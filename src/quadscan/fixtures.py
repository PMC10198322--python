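"""Deterministic generators for sequences and melting curves.

Everything here is seeded and byte-reproducible (NumPy PCG64 generators
with integer seeds), so scanner recall, classifier and melt-fit recovery
studies run without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .melt import CELSIUS_OFFSET, Baselines, MeltCurve, fraction_folded
from .projection import SequenceRecord

__all__ = [
    "FixtureSpec",
    "make_repeat_oligo",
    "make_random_genome",
    "make_spiked_genome",
    "simulate_melt",
]

_BASES = np.array(list("ACGT"))


def make_repeat_oligo(unit: str, count: int) -> SequenceRecord:
    """A pure dinucleotide repeat oligo, named ``(UNIT)_count``.

    ``make_repeat_oligo("GT", 6)`` is the 12-nt oligo GTGTGTGTGTGT.
    """
    unit = unit.upper()
    if count < 1:
        raise ValueError("count must be >= 1")
    if not set(unit) <= set("ACGT"):
        raise ValueError(f"invalid unit {unit!r}")
    return SequenceRecord(id=f"({unit})_{count}", seq=unit * count)


def make_random_genome(
    seed: int, length: int, gc: float = 0.5, id: str | None = None
) -> SequenceRecord:
    """I.i.d. random background with the given GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SequenceRecord(id=id or f"random_{seed}", seq=seq)


def make_spiked_genome(
    seed: int,
    length: int,
    spikes: Sequence[tuple[SequenceRecord, int]],
    gc: float = 0.5,
    id: str | None = None,
) -> tuple[SequenceRecord, list[dict]]:
    """Random background with motifs inserted at fixed 0-based offsets.

    Returns the genome and a truth table of dicts with keys ``record_id``,
    ``start``, ``end``, ``name`` (BED-like, 0-based half-open).  Spikes
    that overlap each other or fall outside the background are rejected.
    """
    genome = make_random_genome(seed, length, gc, id=id or f"spiked_{seed}")
    placed: list[tuple[int, int, str]] = []
    for spike, pos in sorted(spikes, key=lambda x: x[1]):
        start, end = pos, pos + spike.n
        if start < 0 or end > length:
            raise ValueError(f"spike {spike.id} at {pos} falls outside background")
        if placed and start < placed[-1][1]:
            raise ValueError(f"spike {spike.id} at {pos} overlaps previous spike")
        placed.append((start, end, spike.id))
    seq = list(genome.seq)
    truth = []
    for (start, end, name), (spike, _pos) in zip(
        placed, sorted(spikes, key=lambda x: x[1])
    ):
        seq[start:end] = spike.seq
        truth.append(
            {"record_id": genome.id, "start": start, "end": end, "name": name}
        )
    return SequenceRecord(id=genome.id, seq="".join(seq)), truth


def simulate_melt(
    tm_celsius: float,
    dh_kj_mol: float,
    baselines: Baselines = Baselines(1.0, 0.0, 0.0, 0.0),
    noise: float = 0.0,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    molecularity: int = 1,
) -> MeltCurve:
    """Synthesize a two-state melting curve on a temperature grid (C).

    ``noise`` is the Gaussian standard deviation as a fraction of the
    transition amplitude (the folded/unfolded baseline separation at Tm).
    The default grid is 201 points over 0-100 C.
    """
    t = np.linspace(0.0, 100.0, 201) if grid is None else np.asarray(grid, float)
    bf, mf, bu, mu = baselines
    f = fraction_folded(
        t + CELSIUS_OFFSET, tm_celsius + CELSIUS_OFFSET, dh_kj_mol, molecularity
    )
    s = (bf + mf * t) * f + (bu + mu * t) * (1.0 - f)
    if noise > 0:
        amplitude = abs((bf + mf * tm_celsius) - (bu + mu * tm_celsius))
        if amplitude == 0:
            amplitude = np.ptp(s) or 1.0
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise * amplitude, size=t.size)
    return MeltCurve(
        t,
        s,
        {
            "tm_true": tm_celsius,
            "dh_true": dh_kj_mol,
            "noise": noise,
            "seed": seed,
            "molecularity": molecularity,
        },
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture: identical spec => byte-identical output.

    ``kind`` is one of ``repeat_oligo``, ``random_genome``,
    ``spiked_genome``, ``melt_curve``; ``params`` are the keyword arguments
    of the matching ``make_*``/``simulate_melt`` call (spiked-genome spikes
    given as ``[(unit, count, position), ...]``).
    """

    seed: int
    kind: str
    params: tuple = field(default_factory=tuple)

    def build(self):
        params = dict(self.params)
        if self.kind == "repeat_oligo":
            return make_repeat_oligo(**params)
        if self.kind == "random_genome":
            return make_random_genome(seed=self.seed, **params)
        if self.kind == "spiked_genome":
            spikes = [
                (make_repeat_oligo(u, c), pos) for u, c, pos in params.pop("spikes")
            ]
            return make_spiked_genome(seed=self.seed, spikes=spikes, **params)
        if self.kind == "melt_curve":
            return simulate_melt(seed=self.seed, **params)
        raise ValueError(f"unknown fixture kind {self.kind!r}")
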