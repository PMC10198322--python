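"""The validated oligonucleotide set used to calibrate the height model.

Nine oligos: GT and GA dinucleotide repeats of 6/9/18/27 units and the
31-nt VK motif (a GGGAGCGA-repeat that forms a non-G4 tetrahelical
structure and anchors the 0.7-1.1 score band).  These are the sequences
against which the signed-height assignment (G=+3, C=-3, T=+3 sin psi,
A=-3 sin psi, signed trapezoid area) was fixed.
"""

from __future__ import annotations

from .fixtures import make_repeat_oligo
from .projection import SequenceRecord

__all__ = ["VK_SEQUENCE", "reference_oligos"]

VK_SEQUENCE = "GGGAGCGAGGGAGCGAGGGAGCGAGGGAGCG"


def reference_oligos() -> dict[str, SequenceRecord]:
    """Name -> record for the nine calibration oligos."""
    out: dict[str, SequenceRecord] = {}
    for unit in ("GT", "GA"):
        for count in (6, 9, 18, 27):
            rec = make_repeat_oligo(unit, count)
            out[rec.id] = rec
    out["VK"] = SequenceRecord(id="VK", seq=VK_SEQUENCE)
    return out
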