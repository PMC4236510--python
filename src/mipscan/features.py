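"""Per-sequence feature extraction.

NPA boxes, Ar/R selectivity filter, isoelectric point, molecular weight,
loop-D metrics, loop-E motif class / salt bridge, interface conservation and
the three-criterion MIP validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from mipscan.anchor_align import AlignmentResult, ReferenceAnnotation, map_positions
from mipscan.io_core import ProteinSequence
from mipscan.topology import TopologyMap


class FeatureError(RuntimeError):
    """Raised when a feature cannot be computed for a sequence."""


# ---------------------------------------------------------------------------
# constants

CHARGED_RESIDUES = frozenset("DEKR")  # H excluded: ambiguous protonation
SMALL_WEAKLY_POLAR = frozenset("GASTC")

#: Average residue masses (Da); add one water per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Side-chain and terminal pKa sets for pI computation.
PKA_SETS = {
    # Bjellqvist et al. (as popularized by ExPASy), single-value form
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
    "sillero": {
        "Nterm": 8.2, "Cterm": 3.2,
        "K": 10.4, "R": 12.0, "H": 6.4,
        "D": 4.0, "E": 4.5, "C": 9.0, "Y": 10.0,
    },
}

MOTIF_CLASSES = ("AQGP-core", "AQGP-delta", "AQP-type", "XIP-type", "none")


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class NpaBox:
    """One of the two NPA(-like) boxes; ``loop`` is 'B' or 'E'."""

    loop: str
    triplet: str
    canonical: bool
    substituted_offsets: FrozenSet[int]

    @staticmethod
    def from_triplet(loop: str, triplet: str) -> "NpaBox":
        subs = frozenset(i for i, (a, b) in enumerate(zip(triplet, "NPA")) if a != b)
        return NpaBox(loop=loop, triplet=triplet, canonical=not subs, substituted_offsets=subs)


@dataclass(frozen=True)
class ArRFilter:
    """The four aromatic/arginine selectivity-filter residues (None = unmapped)."""

    tm2: Optional[str]
    tm5: Optional[str]
    le1: Optional[str]
    le2: Optional[str]

    @property
    def complete(self) -> bool:
        return None not in (self.tm2, self.tm5, self.le1, self.le2)

    def as_tuple(self) -> Tuple[Optional[str], ...]:
        return (self.tm2, self.tm5, self.le1, self.le2)


@dataclass
class FeatureVector:
    """All derived per-sequence features."""

    seq_id: str
    length: int
    pI: float
    mw: float
    npa_b: NpaBox
    npa_e: NpaBox
    arr: ArRFilter
    loop_d_length: Optional[int]
    loop_d_charged: Optional[int]
    loop_e_motif_class: str
    salt_bridge: bool
    interface_conserved: int
    is_mip: bool = False
    reasons: List[str] = field(default_factory=list)
    ref_id: str = ""
    anchor_identity: float = 0.0


# ---------------------------------------------------------------------------
# anchored feature extraction

def _mapped_residue(seq: ProteinSequence, idx: Optional[int]) -> Optional[str]:
    return seq.residues[idx] if idx is not None else None


def locate_npa_boxes(
    query: ProteinSequence,
    aln: AlignmentResult,
    ref: ReferenceAnnotation,
) -> Tuple[NpaBox, NpaBox]:
    """Read the query triplets at the anchor-mapped NPA box positions.

    A position mapping to a gap is recorded as X and counted substituted. If
    both boxes are wholly unmappable the sequence is likely not MIP-like and a
    :class:`FeatureError` is raised.
    """
    positions = list(range(ref.npa_b_pos, ref.npa_b_pos + 3)) + list(
        range(ref.npa_e_pos, ref.npa_e_pos + 3)
    )
    mapped = map_positions(aln, positions)
    trip_b = "".join(_mapped_residue(query, i) or "X" for i in mapped[:3])
    trip_e = "".join(_mapped_residue(query, i) or "X" for i in mapped[3:])
    if trip_b == "XXX" and trip_e == "XXX":
        raise FeatureError(f"{query.id}: neither NPA box is mappable onto {ref.ref_id}")
    return NpaBox.from_triplet("B", trip_b), NpaBox.from_triplet("E", trip_e)


def extract_arr_filter(
    query: ProteinSequence,
    aln: AlignmentResult,
    ref: ReferenceAnnotation,
) -> ArRFilter:
    """Query residues at the four mapped Ar/R filter positions (None at gaps)."""
    order = ("TM2", "TM5", "LE1", "LE2")
    mapped = map_positions(aln, [ref.arr_positions[k] for k in order])
    residues = [_mapped_residue(query, i) for i in mapped]
    return ArRFilter(tm2=residues[0], tm5=residues[1], le1=residues[2], le2=residues[3])


def interface_conservation(
    query: ProteinSequence,
    aln: AlignmentResult,
    ref: ReferenceAnnotation,
    group_set: FrozenSet[str] = SMALL_WEAKLY_POLAR,
) -> int:
    """Count of mapped interface positions whose query residue is in ``group_set``.

    Unmappable positions count zero.
    """
    mapped = map_positions(aln, list(ref.interface_positions))
    return sum(
        1 for i in mapped if i is not None and query.residues[i] in group_set
    )


# ---------------------------------------------------------------------------
# physicochemical features

def _net_charge(counts: Dict[str, int], ph: float, pka: Dict[str, float]) -> float:
    pos = 0.0
    for key in ("Nterm", "K", "R", "H"):
        n = 1 if key == "Nterm" else counts.get(key, 0)
        pos += n / (1.0 + 10.0 ** (ph - pka[key]))
    neg = 0.0
    for key in ("Cterm", "D", "E", "C", "Y"):
        n = 1 if key == "Cterm" else counts.get(key, 0)
        neg += n / (1.0 + 10.0 ** (pka[key] - ph))
    return pos - neg


def compute_pi(
    seq: Union[ProteinSequence, str],
    pka_set: str = "bjellqvist",
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: pH where the Henderson-Hasselbalch net charge is zero.

    Solved by bisection on [0, 14] to ``tol``; X residues are ignored.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if not residues:
        raise ValueError("compute_pi requires a non-empty sequence")
    pka = PKA_SETS[pka_set]
    counts = {aa: residues.count(aa) for aa in "KRHDECY"}
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_mw(seq: Union[ProteinSequence, str], on_x: str = "raise") -> float:
    """Average-mass molecular weight: sum of residue masses plus one water.

    ``on_x`` controls X handling: 'raise' (default) or 'estimate' (use the
    mean of the twenty residue masses).
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if not residues:
        raise ValueError("compute_mw requires a non-empty sequence")
    mean_mass = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)
    total = WATER_MASS
    for ch in residues:
        if ch == "X":
            if on_x == "raise":
                raise ValueError("sequence contains X; exact mass undefined")
            total += mean_mass
        else:
            total += AVERAGE_RESIDUE_MASS[ch]
    return total


# ---------------------------------------------------------------------------
# loop features

def loop_d_metrics(
    seq: Union[ProteinSequence, str],
    topo: TopologyMap,
) -> Tuple[int, int]:
    """(length, charged-residue count) of loop D (between TM4 and TM5)."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if topo.n_tm < 5:
        raise FeatureError(f"loop D undefined with {topo.n_tm} TM spans (need >= 5)")
    start = topo.tm_spans[3][1]
    end = topo.tm_spans[4][0]
    segment = residues[start:end]
    charged = sum(1 for ch in segment if ch in CHARGED_RESIDUES)
    return len(segment), charged


def classify_motif_window(window: str) -> str:
    """Classify a 6-residue loop-E window by fixed pattern precedence.

    AQGP-core (R,D,x,G,P,R) > AQGP-delta (R,D,x,G,not-P,R) >
    XIP-type (R,C,x,G/A,x,x) > AQP-type (R,S/A,x,G,P/A,x) > none.
    """
    if len(window) != 6:
        return "none"
    w = window
    if w[0] == "R" and w[1] == "D" and w[3] == "G" and w[5] == "R":
        return "AQGP-core" if w[4] == "P" else "AQGP-delta"
    if w[0] == "R" and w[1] == "C" and w[3] in "GA":
        return "XIP-type"
    if w[0] == "R" and w[1] in "SA" and w[3] == "G" and w[4] in "PA":
        return "AQP-type"
    return "none"


def has_salt_bridge(window: str) -> bool:
    """True iff an acidic residue at offset i pairs with a basic one at i+4."""
    return any(
        window[i] in "DE" and window[i + 4] in "KR"
        for i in range(len(window) - 4)
    )


def detect_loop_e_motif(
    seq: Union[ProteinSequence, str],
    region: Tuple[int, int],
) -> Tuple[str, bool]:
    """Scan the 6-residue window following the loop-E NPA box.

    ``region`` is the [start, end) interval of the window on the query. If the
    window extends past the sequence the class is 'none'.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    start, end = region
    if start < 0 or end > len(residues) or end - start < 6:
        return "none", False
    window = residues[start : start + 6]
    return classify_motif_window(window), has_salt_bridge(window)


# ---------------------------------------------------------------------------
# validation

def validate_mip(
    seq: ProteinSequence,
    fv: FeatureVector,
    topo: TopologyMap,
    min_conserved: int = 9,
) -> Tuple[bool, List[str]]:
    """Three-criterion MIP validation.

    (a) both NPA boxes locatable (canonical or NPA-like), (b) exactly six TM
    spans with non-empty LB and LE loops, (c) interface conservation at or
    above ``min_conserved`` of the annotated interface positions.
    """
    reasons: List[str] = []
    if fv.npa_b.triplet == "XXX" or fv.npa_e.triplet == "XXX":
        reasons.append("criterion-a")
    if topo.n_tm != 6:
        reasons.append("criterion-b")
    else:
        lb = topo.loop_spans.get("LB", (0, 0))
        le = topo.loop_spans.get("LE", (0, 0))
        if lb[1] - lb[0] < 1 or le[1] - le[0] < 1:
            reasons.append("criterion-b")
    if fv.interface_conserved < min_conserved:
        reasons.append("criterion-c")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# position-frequency matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def position_frequency_matrix(
    seqs: Sequence[ProteinSequence],
    anchors: Sequence[Tuple[AlignmentResult, ReferenceAnnotation]],
    offsets: Iterable[int] = range(-3, 9),
) -> pd.DataFrame:
    """Residue counts at positions relative to the loop-E NPA asparagine.

    Offset 0 is the N of the loop-E box; rows are offsets, columns amino
    acids. Unmapped positions are skipped.
    """
    offsets = list(offsets)
    counts = {off: {aa: 0 for aa in AA20} for off in offsets}
    for seq, (aln, ref) in zip(seqs, anchors):
        ref_positions = [ref.npa_e_pos + off for off in offsets]
        valid = [
            (off, p) for off, p in zip(offsets, ref_positions)
            if 0 <= p < len(ref.sequence.residues)
        ]
        mapped = map_positions(aln, [p for _, p in valid])
        for (off, _), qi in zip(valid, mapped):
            if qi is not None and seq.residues[qi] in counts[off]:
                counts[off][seq.residues[qi]] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=list(AA20))
    df.index.name = "offset_from_npa_e_N"
    return df
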