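"""Semi-orthogonal sequence geometry and the Qs area score.

A DNA strand is drawn as a polyline: nucleotides sit at unit spacing along
an axis, and each base contributes a signed height on the G/C projection
plane (the sigma plane).  G and C, being complementary, point in opposite
directions at full amplitude.  A and T live on a second plane inclined at
``alpha = 90 - psi`` degrees to the first; their cross-projection onto the
sigma axis therefore scales with ``sin(psi)`` — zero when the planes are
orthogonal (``psi = 0``), growing as the planes tilt toward each other.

The Qs score of a sequence is the signed trapezoid area under the polyline
joining consecutive heights, divided by the number of nucleotides::

    Qs = (1/n) * sum_{i=1}^{n-1} (h_i + h_{i+1}) / 2

G-rich stretches push the polyline up, C-rich stretches pull it down, and
A/T modulate it in proportion to ``sin(psi)``.  High positive Qs marks
G-quadruplex-prone sequence, strongly negative Qs marks the C-rich mirror
(i-motif-prone) on the same strand.  The score is exactly antisymmetric
under complementation and invariant under reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLACEHOLDER",
    "ProjectionModel",
    "SequenceRecord",
    "ScoreProfile",
    "complement",
    "reverse_complement",
    "normalize_sequence",
    "qs_score",
    "qs_components",
]

#: Neutral placeholder written in place of ambiguity codes; height 0.
PLACEHOLDER = "N"

_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")


def complement(seq: str) -> str:
    """Base-wise complement (A<->T, G<->C, placeholder fixed)."""
    return seq.translate(_COMPLEMENT_TABLE)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class ProjectionModel:
    """Signed per-base height assignment on the sigma (G/C) projection axis.

    Parameters
    ----------
    psi_degrees:
        Inclination from orthogonality of the two projection planes,
        ``0 <= psi < 90``.  The default 30 degrees (plane angle
        ``alpha = 60``) is the setting at which the G4 score bands below
        are defined.
    amplitude:
        Base vector magnitude ``A0`` (dimensionless).  The score bands
        assume the default 3.0.

    Heights: ``h(G) = +A0``, ``h(C) = -A0``, ``h(T) = +A0 sin(psi)``,
    ``h(A) = -A0 sin(psi)``, placeholder ``N`` -> 0.  Complementary bases
    always have opposite heights.
    """

    psi_degrees: float = 30.0
    amplitude: float = 3.0
    _table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_degrees < 90.0:
            raise ValueError(f"psi must lie in [0, 90): got {self.psi_degrees}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        s = math.sin(math.radians(self.psi_degrees))
        table = np.zeros(128, dtype=float)
        table[ord("G")] = self.amplitude
        table[ord("C")] = -self.amplitude
        table[ord("T")] = self.amplitude * s
        table[ord("A")] = -self.amplitude * s
        object.__setattr__(self, "_table", table)

    @property
    def alpha_degrees(self) -> float:
        """Angle between the two projection planes; ``alpha + psi = 90``."""
        return 90.0 - self.psi_degrees

    def height(self, base: str) -> float:
        """Signed sigma-axis height of a single (normalized) base."""
        if base not in "ACGTN" or len(base) != 1:
            raise ValueError(f"unnormalized base {base!r}")
        return float(self._table[ord(base)])

    def heights(self, seq: str) -> np.ndarray:
        """Vector of signed heights for a normalized sequence."""
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return self._table[codes]


@dataclass(frozen=True)
class SequenceRecord:
    """A normalized DNA sequence: uppercase A/C/G/T plus ``N`` placeholders.

    ``replaced`` counts characters that were outside {A, C, G, T, U} in the
    raw input and were mapped to the neutral placeholder.
    """

    id: str
    seq: str
    replaced: int = 0

    @property
    def n(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.seq), self.replaced)


def normalize_sequence(raw: str, id: str = "seq") -> SequenceRecord:
    """Normalize arbitrary sequence text to a :class:`SequenceRecord`.

    Whitespace is stripped, case folded, and RNA ``U`` mapped to ``T``.
    Any remaining character outside {A, C, G, T} becomes the neutral
    placeholder (height 0) and is counted in ``replaced`` — lossy
    normalization is recorded, never fatal, so genome-scale FASTA input
    with ambiguity codes scans without aborting.
    """
    compact = "".join(raw.split()).upper().replace("U", "T")
    out = []
    replaced = 0
    for ch in compact:
        if ch in _VALID:
            out.append(ch)
        else:
            out.append(PLACEHOLDER)
            replaced += 1
    return SequenceRecord(id=id, seq="".join(out), replaced=replaced)


@dataclass(frozen=True)
class ScoreProfile:
    """Per-window Qs values over one record.

    Windows are ``(start, end, qs)`` with 0-based half-open coordinates,
    sorted by start.
    """

    record_id: str
    psi_degrees: float
    window_size: int
    step: int
    windows: tuple[tuple[int, int, float], ...]

    def __len__(self) -> int:
        return len(self.windows)

    def scores(self) -> np.ndarray:
        return np.array([w[2] for w in self.windows], dtype=float)


def _as_seq(rec: SequenceRecord | str) -> str:
    return rec.seq if isinstance(rec, SequenceRecord) else rec


def qs_score(rec: SequenceRecord | str, model: ProjectionModel | None = None) -> float:
    """Signed trapezoid area under the height polyline per nucleotide.

    Sequences of length <= 1 subtend no area and score 0.
    """
    seq = _as_seq(rec)
    n = len(seq)
    if n <= 1:
        return 0.0
    model = model or ProjectionModel()
    h = model.heights(seq)
    return float(0.5 * (h[:-1] + h[1:]).sum() / n)


def qs_components(
    rec: SequenceRecord | str, amplitude: float = 3.0
) -> tuple[float, float]:
    """Decompose the score into its G/C and A/T parts.

    Returns ``(qs_gc, qs_at)`` such that ``Qs(psi) = qs_gc +
    sin(psi) * qs_at`` exactly for every psi: ``qs_gc`` scores with A/T
    heights zeroed, ``qs_at`` with G/C zeroed and A/T at full ``+/-A0``.
    """
    seq = _as_seq(rec)
    n = len(seq)
    if n <= 1:
        return 0.0, 0.0
    gc = np.zeros(128)
    gc[ord("G")] = amplitude
    gc[ord("C")] = -amplitude
    at = np.zeros(128)
    at[ord("T")] = amplitude
    at[ord("A")] = -amplitude
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    h_gc = gc[codes]
    h_at = at[codes]
    qs_gc = float(0.5 * (h_gc[:-1] + h_gc[1:]).sum() / n)
    qs_at = float(0.5 * (h_at[:-1] + h_at[1:]).sum() / n)
    return qs_gc, qs_at
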