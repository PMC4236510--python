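"""Global pairwise alignment against annotated reference channels.

Queries are mapped onto annotated anchor sequences (water-channel-, glycerol-
channel- and SIP-type anchors, standing in for the structural templates used
in homology modeling) by Needleman-Wunsch alignment with affine gaps; feature
positions (NPA boxes, Ar/R filter, interface positions) are then read off the
query through the alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

from Bio.Align import PairwiseAligner, substitution_matrices

from mipscan.io_core import ProteinSequence

Span = Tuple[int, int]

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class ReferenceAnnotation:
    """An annotated anchor sequence used for position mapping.

    ``arr_positions`` holds the four selectivity-filter indices keyed
    TM2/TM5/LE1/LE2; ``interface_positions`` the (by default 17) helix-helix
    interface indices; ``npa_b_pos``/``npa_e_pos`` the starts of the two
    3-residue NPA boxes.  All coordinates are 0-based on the anchor sequence.
    """

    ref_id: str
    sequence: ProteinSequence
    tm_spans: Tuple[Span, ...]
    npa_b_pos: int
    npa_e_pos: int
    arr_positions: Dict[str, int]
    interface_positions: Tuple[int, ...]
    loop_e_motif_span: Span

    def __post_init__(self) -> None:
        res = self.sequence.residues
        for pos, name in ((self.npa_b_pos, "B"), (self.npa_e_pos, "E")):
            if res[pos : pos + 3] != "NPA":
                raise ValueError(
                    f"reference {self.ref_id!r}: residues at NPA box {name} "
                    f"({pos}) are {res[pos:pos + 3]!r}, expected 'NPA'"
                )
        if len(self.tm_spans) == 6:
            tm2, tm5 = self.tm_spans[1], self.tm_spans[4]
            le = (self.tm_spans[4][1], self.tm_spans[5][0])
            p = self.arr_positions
            if not (tm2[0] <= p["TM2"] < tm2[1]):
                raise ValueError(f"reference {self.ref_id!r}: TM2 filter index outside TM span 2")
            if not (tm5[0] <= p["TM5"] < tm5[1]):
                raise ValueError(f"reference {self.ref_id!r}: TM5 filter index outside TM span 5")
            if not (le[0] <= p["LE1"] < p["LE2"] < le[1]):
                raise ValueError(f"reference {self.ref_id!r}: LE1/LE2 must lie in loop E with LE1 < LE2")


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with identity/similarity fractions.

    ``identity`` counts matching columns over mutually non-gap columns (an X
    never counts as a match); ``similarity`` counts positive-substitution-score
    columns over the same denominator.
    """

    aligned_query: str
    aligned_ref: str
    score: float
    identity: float
    similarity: float

    def identity_over(self, denominator: str = "nongap") -> float:
        """Identity with a configurable denominator: 'nongap' or 'columns'."""
        matches = sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_ref)
            if a == b and a not in ("-", "X")
        )
        if denominator == "columns":
            return matches / len(self.aligned_query)
        if denominator == "nongap":
            nongap = sum(
                1 for a, b in zip(self.aligned_query, self.aligned_ref) if a != "-" and b != "-"
            )
            return matches / nongap if nongap else 0.0
        raise ValueError(f"unknown denominator {denominator!r}")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    return aligner


def global_align(
    a: Union[ProteinSequence, str],
    b: Union[ProteinSequence, str],
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment with affine gap penalties."""
    sa = a.residues if isinstance(a, ProteinSequence) else a
    sb = b.residues if isinstance(b, ProteinSequence) else b
    if not sa or not sb:
        raise ValueError("global_align requires two non-empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(sa, sb)[0]
    qrow, rrow = str(aln[0]), str(aln[1])
    subs = aligner.substitution_matrix
    matches = 0
    positive = 0
    nongap = 0
    for x, y in zip(qrow, rrow):
        if x == "-" or y == "-":
            continue
        nongap += 1
        if x == y and x != "X":
            matches += 1
        if subs[x, y] > 0:
            positive += 1
    identity = matches / nongap if nongap else 0.0
    similarity = positive / nongap if nongap else 0.0
    return AlignmentResult(
        aligned_query=qrow,
        aligned_ref=rrow,
        score=float(aln.score),
        identity=identity,
        similarity=similarity,
    )


def choose_reference(
    query: ProteinSequence,
    refs: Sequence[ReferenceAnnotation],
    **align_kwargs,
) -> Tuple[ReferenceAnnotation, AlignmentResult]:
    """Pick the annotated reference with the best alignment score.

    Ties are broken by lexicographic ``ref_id``.
    """
    if not refs:
        raise ValueError("choose_reference requires at least one reference")
    best: Optional[Tuple[float, str, ReferenceAnnotation, AlignmentResult]] = None
    for ref in sorted(refs, key=lambda r: r.ref_id):
        aln = global_align(query, ref.sequence, **align_kwargs)
        if best is None or aln.score > best[0]:
            best = (aln.score, ref.ref_id, ref, aln)
    return best[2], best[3]


def map_position(aln: AlignmentResult, ref_pos: int) -> Optional[int]:
    """Query index aligned to reference position ``ref_pos`` (None at a gap)."""
    ref_len = sum(1 for c in aln.aligned_ref if c != "-")
    if not (0 <= ref_pos < ref_len):
        raise ValueError(f"ref_pos {ref_pos} out of range (reference length {ref_len})")
    qi = 0
    ri = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if rc != "-":
            if ri == ref_pos:
                return qi if qc != "-" else None
            ri += 1
        if qc != "-":
            qi += 1
    raise AssertionError("unreachable")  # pragma: no cover


def map_positions(aln: AlignmentResult, ref_positions: Sequence[int]) -> List[Optional[int]]:
    """Vector form of :func:`map_position` (single pass over the alignment)."""
    ref_len = sum(1 for c in aln.aligned_ref if c != "-")
    for p in ref_positions:
        if not (0 <= p < ref_len):
            raise ValueError(f"ref_pos {p} out of range (reference length {ref_len})")
    table: List[Optional[int]] = [None] * ref_len
    qi = 0
    ri = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if rc != "-":
            table[ri] = qi if qc != "-" else None
            ri += 1
        if qc != "-":
            qi += 1
    return [table[p] for p in ref_positions]


def _annotation_from_dict(d: dict) -> ReferenceAnnotation:
    seq = ProteinSequence(id=d["ref_id"], residues=d["sequence"], description=d.get("description", ""))
    return ReferenceAnnotation(
        ref_id=d["ref_id"],
        sequence=seq,
        tm_spans=tuple((int(s), int(e)) for s, e in d["tm_spans"]),
        npa_b_pos=int(d["npa_b_pos"]),
        npa_e_pos=int(d["npa_e_pos"]),
        arr_positions={k: int(v) for k, v in d["arr_positions"].items()},
        interface_positions=tuple(int(p) for p in d["interface_positions"]),
        loop_e_motif_span=tuple(d["loop_e_motif_span"]),  # type: ignore[arg-type]
    )


def load_references(path) -> List[ReferenceAnnotation]:
    """Load reference annotations from a JSON file (see data/references.json)."""
    with open(path) as fh:
        payload = json.load(fh)
    return [_annotation_from_dict(d) for d in payload["references"]]


def load_default_references() -> List[ReferenceAnnotation]:
    """Load the annotation set shipped with the package."""
    ref = resources.files("mipscan").joinpath("data/references.json")
    payload = json.loads(ref.read_text())
    return [_annotation_from_dict(d) for d in payload["references"]]
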