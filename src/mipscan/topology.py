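"""Six-TM + loop topology assignment from hydropathy, or imported spans.

Coordinates are 0-based half-open intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from mipscan.io_core import ProteinSequence

# Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
    # X is treated as neutral
    "X": 0.0,
}

#: Canonical loop names for a six-TM MIP topology, in sequence order.
LOOP_NAMES_6TM = ("N-term", "LA", "LB", "LC", "LD", "LE", "C-term")

Span = Tuple[int, int]


@dataclass(frozen=True)
class TopologyMap:
    """Ordered TM spans plus the derived loop spans (termini included).

    ``tm_spans`` are non-overlapping, strictly increasing [start, end) pairs;
    ``loop_spans`` tile the complement.  For a 6-TM map the loops carry the
    canonical names N-term, LA..LE, C-term; otherwise generic L1..Ln names.
    """

    length: int
    tm_spans: Tuple[Span, ...]
    loop_spans: Dict[str, Span] = field(default_factory=dict)

    @property
    def n_tm(self) -> int:
        return len(self.tm_spans)

    def loop(self, name: str) -> Span:
        return self.loop_spans[name]


def _derive_loops(length: int, tm_spans: Sequence[Span]) -> Dict[str, Span]:
    n = len(tm_spans)
    if n == 0:
        return {"N-term": (0, length)}
    loops: Dict[str, Span] = {}
    names: List[str]
    if n == 6:
        names = list(LOOP_NAMES_6TM)
    else:
        names = ["N-term"] + [f"L{i}" for i in range(1, n)] + ["C-term"]
    loops[names[0]] = (0, tm_spans[0][0])
    for i in range(1, n):
        loops[names[i]] = (tm_spans[i - 1][1], tm_spans[i][0])
    loops[names[-1]] = (tm_spans[-1][1], length)
    return loops


def _validate_spans(length: int, spans: Sequence[Span]) -> None:
    prev_end = 0
    for s, e in spans:
        if not (0 <= s < e <= length):
            raise ValueError(f"span ({s}, {e}) out of range for sequence of length {length}")
        if s < prev_end:
            raise ValueError(f"span ({s}, {e}) overlaps or is out of order")
        prev_end = e


def make_topology(length: int, tm_spans: Sequence[Span]) -> TopologyMap:
    """Build a validated :class:`TopologyMap` from TM spans."""
    spans = tuple((int(s), int(e)) for s, e in tm_spans)
    _validate_spans(length, spans)
    return TopologyMap(length=length, tm_spans=spans, loop_spans=_derive_loops(length, spans))


def hydropathy_profile(seq: Union[ProteinSequence, str], window: int = 19) -> np.ndarray:
    """Centered sliding-window mean of Kyte-Doolittle hydropathy values.

    At the termini the window shrinks symmetrically so every residue gets a
    score. ``window`` must be odd and no longer than the sequence.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > n:
        raise ValueError(f"window {window} longer than sequence ({n})")
    values = np.array([KYTE_DOOLITTLE[ch] for ch in residues], dtype=float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.maximum(0, np.arange(n) - half)
    ends = np.minimum(n, np.arange(n) + half + 1)
    return (csum[ends] - csum[starts]) / (ends - starts)


def _split_long_run(start: int, end: int, min_len: int, max_len: int) -> List[Span]:
    """Cut a run longer than ``max_len`` into pieces within [min_len, max_len].

    Pieces are equal-sized (remainder spread from the left); if equal splitting
    cannot keep every piece >= min_len the run is trimmed centrally to max_len.
    """
    length = end - start
    k = -(-length // max_len)  # ceil
    if length // k < min_len:
        mid = (start + end) // 2
        return [(mid - max_len // 2, mid - max_len // 2 + max_len)]
    base, rem = divmod(length, k)
    out = []
    pos = start
    for i in range(k):
        size = base + (1 if i < rem else 0)
        out.append((pos, pos + size))
        pos += size
    return out


def predict_topology(
    seq: Union[ProteinSequence, str],
    threshold: float = 1.6,
    min_len: int = 15,
    max_len: int = 30,
    window: int = 19,
) -> TopologyMap:
    """Predict TM spans as maximal hydropathy runs above ``threshold``.

    Runs shorter than ``min_len`` are discarded; longer than ``max_len`` are
    split/trimmed (see :func:`_split_long_run`). Loops are the complement.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n < min_len:
        raise ValueError(f"sequence length {n} shorter than min_len {min_len}")
    profile = hydropathy_profile(residues, window=window)
    above = profile >= threshold
    spans: List[Span] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            run_len = j - i
            if run_len >= min_len:
                if run_len > max_len:
                    spans.extend(_split_long_run(i, j, min_len, max_len))
                else:
                    spans.append((i, j))
            i = j
        else:
            i += 1
    return make_topology(n, spans)


def import_topology(seq: Union[ProteinSequence, str], spans: Sequence[Span]) -> TopologyMap:
    """Build a :class:`TopologyMap` verbatim from externally supplied spans.

    Overlapping, unsorted or out-of-range spans raise ``ValueError``.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    return make_topology(len(residues), spans)
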