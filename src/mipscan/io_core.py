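"""Sequence records, FASTA I/O and redundancy removal."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_STRIP_RE = re.compile(r"[\s\d]+")


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be parsed into a valid protein sequence."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence record.

    ``residues`` is an uppercase string over the 20 one-letter codes plus X.
    """

    id: str
    residues: str
    description: str = ""
    taxon_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        for pos, ch in enumerate(self.residues):
            if ch not in VALID_RESIDUES:
                raise FastaParseError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_body(body: str) -> str:
    return _STRIP_RE.sub("", body).upper()


def read_fasta(path) -> List[ProteinSequence]:
    """Read a multi-record FASTA file into a list of :class:`ProteinSequence`.

    Residues are uppercased; whitespace and digits are stripped. Record order is
    preserved. A malformed header, an illegal residue or a duplicate id raises
    :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[ProteinSequence] = []
    seen: set = set()
    header: Optional[str] = None
    body_parts: List[str] = []

    def _flush() -> None:
        if header is None:
            return
        tokens = header.split(None, 1)
        if not tokens:
            raise FastaParseError("malformed header: empty after '>'")
        rec_id = tokens[0]
        desc = tokens[1].strip() if len(tokens) > 1 else ""
        body = _normalize_body("".join(body_parts))
        if not body:
            raise FastaParseError(f"record {rec_id!r}: empty sequence body")
        if rec_id in seen:
            raise FastaParseError(f"duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(ProteinSequence(id=rec_id, residues=body, description=desc))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                body_parts = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                body_parts.append(line)
    _flush()
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path, width: int = 60) -> None:
    """Write records to ``path`` in FASTA, wrapping lines at ``width`` columns."""
    with open(path, "w") as fh:
        for seq in seqs:
            header = seq.id if not seq.description else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def dedup_sequences(
    seqs: List[ProteinSequence],
    identity_threshold: float = 1.0,
) -> Tuple[List[ProteinSequence], Dict[str, str]]:
    """Greedy redundancy removal (CD-HIT-like, reimplemented).

    Sequences are visited in descending length order (ties broken by id); a
    sequence is dropped when its pairwise identity to an already-kept sequence
    reaches ``identity_threshold``. Identity here uses the full-alignment-length
    denominator so a threshold of 1.0 only ever removes exact duplicates.

    Returns the kept list (greedy visit order) and a map removed-id -> retained-id.
    """
    from mipscan.anchor_align import global_align

    if not seqs:
        raise ValueError("dedup_sequences requires at least one sequence")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")

    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    kept: List[ProteinSequence] = []
    removed_map: Dict[str, str] = {}
    for seq in ordered:
        hit: Optional[ProteinSequence] = None
        for ref in kept:
            aln = global_align(seq, ref)
            if aln.identity_over("columns") >= identity_threshold:
                hit = ref
                break
        if hit is None:
            kept.append(seq)
        else:
            removed_map[seq.id] = hit.id
    return kept, removed_map
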