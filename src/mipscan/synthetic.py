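"""Labeled synthetic MIP-like sequence generator.

Sequences follow the six-TM hourglass architecture: hydrophobic TM blocks
separated by hydrophilic loops, NPA boxes planted in loops B and E, the four
Ar/R filter residues at anchor-consistent positions, a 6-residue loop-E motif
window after the loop-E box, charged residues in loop D, and small residues at
the helix-helix interface positions.

Every subfamily shares a family-wide backbone; each subfamily then diverges at
a fixed fraction of non-planted positions (deterministically, from the label),
so that within-subfamily identity is high, between-subfamily identity is lower
and tree-based clustering has signal. Per-sequence variation comes from the
planted-feature draws and an optional background mutation rate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from mipscan.io_core import ProteinSequence

Span = Tuple[int, int]

# ---------------------------------------------------------------------------
# architecture

TM_LENGTH = 21
SEGMENT_ORDER = (
    "N-term", "TM1", "LA", "TM2", "LB", "TM3", "LC", "TM4", "LD", "TM5", "LE", "TM6", "C-term",
)
BASE_LOOP_LENGTHS = {
    "N-term": 12, "LA": 10, "LB": 14, "LC": 16, "LD": 12, "LE": 20, "C-term": 12,
}

# offsets inside segments
NPA_B_OFFSET = 3          # loop B: box at LB[3:6]
LE1_OFFSET = 2            # loop E: LE1 three positions before the box N
NPA_E_OFFSET = 5          # loop E: box at LE[5:8]
MOTIF_OFFSET = 8          # loop E: 6-residue window at LE[8:14]; offset 0 == LE2
ARR_TM2_OFFSET = 15       # filter residue inside TM2
ARR_TM5_OFFSET = 15       # filter residue inside TM5
INTERFACE_OFFSETS = {
    "TM1": (4, 10, 18), "TM2": (4, 10, 18), "TM3": (4, 10, 18),
    "TM4": (4, 10, 18), "TM5": (4, 10, 18), "TM6": (4, 10),
}  # 17 positions total

TM_ALPHABET = "ILV"              # strongly hydrophobic core
LOOP_ALPHABET = "STNQDEGKRHP"    # hydrophilic
INTERFACE_ALPHABET = "AG"        # small / weakly polar
CHARGED = "DEKR"

SUBFAMILY_LABELS = (
    "AQP", "Fps1-like", "Yfl054-like", "alpha", "beta",
    "gamma1", "gamma2", "delta", "XIP", "SIP-like",
)

AQGP_LABELS = ("Fps1-like", "Yfl054-like", "alpha", "beta", "gamma1", "gamma2", "delta")

# per-subfamily loop-length overrides; AQGPs get long termini, the SIP-like
# group is deliberately small with the longest, most charged loop D
_LOOP_OVERRIDES: Dict[str, Dict[str, int]] = {
    **{label: {"N-term": 26, "C-term": 20} for label in AQGP_LABELS},
    "AQP": {"N-term": 18, "C-term": 14, "LD": 10},
    "XIP": {"N-term": 22, "C-term": 16},
    "SIP-like": {"N-term": 5, "C-term": 5, "LC": 12, "LD": 22},
}

# NPA substitution behaviour: (box, offset, replacement residues)
_NPA_SUB_SITE: Dict[str, Tuple[str, int, str]] = {
    "Fps1-like": ("E", 1, "LSTA"),
    "Yfl054-like": ("E", 1, "LSTA"),
    "alpha": ("E", 1, "LSTA"),
    "beta": ("E", 1, "LSTA"),
    "gamma1": ("E", 1, "LSTA"),
    "gamma2": ("E", 1, "LSTA"),
    "delta": ("E", 1, "LAST"),      # proline invariably replaced in the LE box
    "AQP": ("B", 2, "STVC"),
    "XIP": ("E", 2, "STVC"),
    "SIP-like": ("E", 2, "STVG"),   # the LE alanine is the substituted position
}

_MOTIF_CLASS: Dict[str, str] = {
    **{label: "AQGP-core" for label in AQGP_LABELS},
    "delta": "AQGP-delta",
    "AQP": "AQP-type",
    "XIP": "XIP-type",
    "SIP-like": "none",
}

_LOOP_D_CHARGE_FRAC: Dict[str, float] = {
    **{label: 0.15 for label in AQGP_LABELS},
    "AQP": 0.10,
    "XIP": 0.15,
    "SIP-like": 0.50,
}

SUBFAMILY_DIVERGENCE = 0.25


def load_rule_sets() -> dict:
    """The packaged per-subfamily filter residue sets and NPA rates."""
    payload = resources.files("mipscan").joinpath("data/rules.json").read_text()
    return json.loads(payload)


# ---------------------------------------------------------------------------
# spec / ground truth

@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to generate one subfamily's sequences."""

    label: str
    loop_lengths: Dict[str, int]
    filter_choice: Dict[str, str]      # position -> allowed residues
    npa_b_sub_rate: float
    npa_e_sub_rate: float
    npa_sub_site: Tuple[str, int, str]
    loop_e_motif_class: str
    loop_d_charge_frac: float
    background_mutation_rate: float = 0.0
    tm_length: int = TM_LENGTH
    divergence: float = SUBFAMILY_DIVERGENCE

    def __post_init__(self) -> None:
        for name, rate in (
            ("npa_b_sub_rate", self.npa_b_sub_rate),
            ("npa_e_sub_rate", self.npa_e_sub_rate),
            ("background_mutation_rate", self.background_mutation_rate),
            ("loop_d_charge_frac", self.loop_d_charge_frac),
            ("divergence", self.divergence),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")

    def segment_lengths(self) -> Dict[str, int]:
        out = {}
        for name in SEGMENT_ORDER:
            out[name] = self.tm_length if name.startswith("TM") else self.loop_lengths[name]
        return out

    def segment_spans(self) -> Dict[str, Span]:
        spans = {}
        pos = 0
        for name, length in self.segment_lengths().items():
            spans[name] = (pos, pos + length)
            pos += length
        return spans

    @property
    def total_length(self) -> int:
        return sum(self.segment_lengths().values())


@dataclass(frozen=True)
class GroundTruth:
    """Planted values for one generated sequence (consistent by construction)."""

    label: str
    tm_spans: Tuple[Span, ...]
    npa_b_triplet: str
    npa_e_triplet: str
    arr: Tuple[str, str, str, str]     # TM2, TM5, LE1, LE2
    motif_class: str
    salt_bridge: bool
    loop_d_length: int
    loop_d_charged: int
    motif_window: str


def make_subfamily_template(
    label: str,
    background_mutation_rate: float = 0.0,
) -> SyntheticSpec:
    """A :class:`SyntheticSpec` parameterized from the packaged rule table."""
    rules = load_rule_sets()["fungal"]
    if label not in rules:
        raise ValueError(f"unknown subfamily label {label!r}; known: {sorted(rules)}")
    row = rules[label]
    loop_lengths = dict(BASE_LOOP_LENGTHS)
    loop_lengths.update(_LOOP_OVERRIDES.get(label, {}))
    box, offset, repl = _NPA_SUB_SITE[label]
    rate = row["npa_sub_pct"] / 100.0
    return SyntheticSpec(
        label=label,
        loop_lengths=loop_lengths,
        filter_choice={k: row[k] for k in ("TM2", "TM5", "LE1", "LE2")},
        npa_b_sub_rate=rate if box == "B" else (0.3 if label == "delta" else 0.0),
        npa_e_sub_rate=rate if box == "E" else 0.0,
        npa_sub_site=(box, offset, repl),
        loop_e_motif_class=_MOTIF_CLASS[label],
        loop_d_charge_frac=_LOOP_D_CHARGE_FRAC[label],
        background_mutation_rate=background_mutation_rate,
    )


# ---------------------------------------------------------------------------
# backbones

def _stable_rng(*tokens: str) -> np.random.Generator:
    digest = hashlib.sha256("|".join(tokens).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _draw(rng: np.random.Generator, alphabet: str) -> str:
    return alphabet[int(rng.integers(len(alphabet)))]


@lru_cache(maxsize=None)
def _family_segment(name: str, length: int) -> str:
    """Family-wide backbone residues for one segment (deterministic)."""
    rng = _stable_rng("mip-family-core", name, str(length))
    alphabet = TM_ALPHABET if name.startswith("TM") else LOOP_ALPHABET
    chars = [_draw(rng, alphabet) for _ in range(length)]
    if name.startswith("TM"):
        for off in INTERFACE_OFFSETS.get(name, ()):
            chars[off] = _draw(rng, INTERFACE_ALPHABET)
    return "".join(chars)


@lru_cache(maxsize=None)
def _subfamily_backbone_cached(
    label: str, lengths_key: tuple, divergence: float
) -> Tuple[str, ...]:
    lengths = dict(lengths_key)
    segments: List[str] = []
    for name in SEGMENT_ORDER:
        length = lengths[name]
        base = _family_segment(name, BASE_LOOP_LENGTHS.get(name, TM_LENGTH))
        chars = list(base)
        alphabet = TM_ALPHABET if name.startswith("TM") else LOOP_ALPHABET
        # subfamily divergence on the base-length segment first, so backbones
        # generated at different segment lengths stay consistent
        reserved = _planted_offsets_by_name(name)
        rng_div = _stable_rng("mip-subfamily-div", label, name)
        for i in range(len(chars)):
            if i in reserved:
                continue
            if rng_div.random() < divergence:
                chars[i] = _draw(rng_div, alphabet)
        # then adjust length: termini grow/shrink distally, loops centrally
        delta = length - len(chars)
        rng_len = _stable_rng("mip-subfamily-len", label, name)
        if delta > 0:
            extra = [_draw(rng_len, alphabet) for _ in range(delta)]
            if name == "N-term":
                chars = extra + chars
            elif name == "C-term":
                chars = chars + extra
            else:
                mid = len(chars) // 2
                chars = chars[:mid] + extra + chars[mid:]
        elif delta < 0:
            if name == "N-term":
                chars = chars[-length:]
            elif name == "C-term":
                chars = chars[:length]
            else:
                chars = chars[: length // 2] + chars[len(chars) - (length - length // 2):]
        segments.append("".join(chars))
    return tuple(segments)


def _planted_offsets_by_name(name: str) -> frozenset:
    out = set()
    if name in INTERFACE_OFFSETS:
        out.update(INTERFACE_OFFSETS[name])
    if name == "TM2":
        out.add(ARR_TM2_OFFSET)
    if name == "TM5":
        out.add(ARR_TM5_OFFSET)
    if name == "LB":
        out.update(range(NPA_B_OFFSET, NPA_B_OFFSET + 3))
    if name == "LE":
        out.add(LE1_OFFSET)
        out.update(range(NPA_E_OFFSET, NPA_E_OFFSET + 3))
        out.update(range(MOTIF_OFFSET, MOTIF_OFFSET + 6))
    return frozenset(out)


def subfamily_backbone(spec: SyntheticSpec) -> Dict[str, str]:
    """Deterministic per-subfamily backbone segments (before per-sequence draws)."""
    lengths_key = tuple(sorted(spec.segment_lengths().items()))
    segs = _subfamily_backbone_cached(spec.label, lengths_key, spec.divergence)
    return dict(zip(SEGMENT_ORDER, segs))


# ---------------------------------------------------------------------------
# per-sequence generation

def _motif_window(spec: SyntheticSpec, le2: str, rng: np.random.Generator) -> str:
    """Plant the 6-residue loop-E window; window[0] is the LE2 filter residue."""
    cls = spec.loop_e_motif_class
    x = _draw(rng, LOOP_ALPHABET)
    if cls == "AQGP-core":
        return f"{le2}D{x}GPR"
    if cls == "AQGP-delta":
        z = _draw(rng, LOOP_ALPHABET.replace("P", ""))
        return f"{le2}D{x}G{z}R"
    if cls == "AQP-type":
        s = _draw(rng, "SA")
        p = _draw(rng, "PA")
        a = _draw(rng, "ACDS")
        return f"{le2}{s}{x}G{p}{a}"
    if cls == "XIP-type":
        g = _draw(rng, "GA")
        y = _draw(rng, LOOP_ALPHABET)
        z = _draw(rng, "YFM")
        return f"{le2}C{x}{g}{y}{z}"
    # no conserved motif: random hydrophilic tail after LE2
    tail = "".join(_draw(rng, LOOP_ALPHABET) for _ in range(5))
    return f"{le2}{tail}"


def generate_sequence(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    seq_id: str = "synthetic",
) -> Tuple[ProteinSequence, GroundTruth]:
    """Generate one sequence plus its ground truth; deterministic for a given rng."""
    if spec.loop_lengths["LB"] < NPA_B_OFFSET + 3:
        raise ValueError("loop B too short for the NPA box")
    if spec.loop_lengths["LE"] < MOTIF_OFFSET + 6:
        raise ValueError("loop E too short for the NPA box and motif window")
    segments = {k: list(v) for k, v in subfamily_backbone(spec).items()}

    # Ar/R filter draws
    tm2 = _draw(rng, spec.filter_choice["TM2"])
    tm5 = _draw(rng, spec.filter_choice["TM5"])
    le1 = _draw(rng, spec.filter_choice["LE1"])
    le2 = _draw(rng, spec.filter_choice["LE2"])
    segments["TM2"][ARR_TM2_OFFSET] = tm2
    segments["TM5"][ARR_TM5_OFFSET] = tm5
    segments["LE"][LE1_OFFSET] = le1

    # NPA boxes
    box_b = list("NPA")
    box_e = list("NPA")
    site_box, site_offset, repl = spec.npa_sub_site
    if rng.random() < spec.npa_b_sub_rate:
        off = site_offset if site_box == "B" else 0
        pool = repl if site_box == "B" else "SH"  # loop-B N -> S/H style substitution
        box_b[off] = _draw(rng, pool)
    if rng.random() < spec.npa_e_sub_rate:
        off = site_offset if site_box == "E" else 2
        pool = repl if site_box == "E" else "STV"
        box_e[off] = _draw(rng, pool)
    segments["LB"][NPA_B_OFFSET : NPA_B_OFFSET + 3] = box_b
    segments["LE"][NPA_E_OFFSET : NPA_E_OFFSET + 3] = box_e

    # loop-E motif window (window[0] is LE2)
    window = _motif_window(spec, le2, rng)
    segments["LE"][MOTIF_OFFSET : MOTIF_OFFSET + 6] = list(window)

    # loop-D charge planting
    ld = segments["LD"]
    n_charged = int(round(spec.loop_d_charge_frac * len(ld)))
    if n_charged:
        positions = rng.choice(len(ld), size=n_charged, replace=False)
        for p in sorted(int(p) for p in positions):
            ld[p] = _draw(rng, CHARGED)

    # background mutations outside planted sites
    if spec.background_mutation_rate > 0.0:
        for name in SEGMENT_ORDER:
            reserved = _planted_offsets_by_name(name)
            alphabet = TM_ALPHABET if name.startswith("TM") else LOOP_ALPHABET
            seg = segments[name]
            for i in range(len(seg)):
                if i in reserved:
                    continue
                if rng.random() < spec.background_mutation_rate:
                    current = seg[i]
                    choices = alphabet.replace(current, "") or alphabet
                    seg[i] = _draw(rng, choices)

    residues = "".join("".join(seg) for seg in (segments[n] for n in SEGMENT_ORDER))
    spans = spec.segment_spans()
    tm_spans = tuple(spans[f"TM{i}"] for i in range(1, 7))
    ld_str = "".join(segments["LD"])
    motif_cls = spec.loop_e_motif_class if window[0] == "R" or spec.loop_e_motif_class == "none" else "none"
    truth = GroundTruth(
        label=spec.label,
        tm_spans=tm_spans,
        npa_b_triplet="".join(box_b),
        npa_e_triplet="".join(box_e),
        arr=(tm2, tm5, le1, le2),
        motif_class=motif_cls,
        salt_bridge=spec.loop_e_motif_class in ("AQGP-core", "AQGP-delta"),
        loop_d_length=len(ld_str),
        loop_d_charged=sum(1 for ch in ld_str if ch in CHARGED),
        motif_window=window,
    )
    seq = ProteinSequence(id=seq_id, residues=residues, description=f"subfamily={spec.label}")
    return seq, truth


def generate_dataset(
    labels: Sequence[str],
    n_per_label: int,
    seed: int = 0,
    background_mutation_rate: float = 0.0,
) -> Tuple[List[ProteinSequence], pd.DataFrame]:
    """Generate ``n_per_label`` sequences per label with counter-derived seeds.

    Returns the records (headers carry ``subfamily=<label>``) and a ground
    truth table, both byte-reproducible for a fixed seed.
    """
    records: List[ProteinSequence] = []
    rows = []
    for li, label in enumerate(labels):
        spec = make_subfamily_template(label, background_mutation_rate)
        for i in range(n_per_label):
            rng = np.random.default_rng([seed, li, i])
            seq_id = f"{label}_{i:03d}"
            seq, truth = generate_sequence(spec, rng, seq_id=seq_id)
            records.append(seq)
            rows.append(
                {
                    "id": seq_id,
                    "label": truth.label,
                    "npa_b": truth.npa_b_triplet,
                    "npa_e": truth.npa_e_triplet,
                    "arr_tm2": truth.arr[0],
                    "arr_tm5": truth.arr[1],
                    "arr_le1": truth.arr[2],
                    "arr_le2": truth.arr[3],
                    "motif_class": truth.motif_class,
                    "salt_bridge": truth.salt_bridge,
                    "loop_d_length": truth.loop_d_length,
                    "loop_d_charged": truth.loop_d_charged,
                    "tm_spans": ";".join(f"{s}-{e}" for s, e in truth.tm_spans),
                }
            )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# anchors and exemplars

ANCHOR_DEFS = (
    ("AQP-anchor", "AQP", "water-channel-type anchor (AQP1/1J4N role)"),
    ("AQGP-anchor", "alpha", "glycerol-channel-type anchor (GlpF/1FX8 role)"),
    ("SIP-anchor", "SIP-like", "small-channel anchor (AQPM/2F2B role)"),
)


def build_anchor(ref_id: str, label: str, description: str = ""):
    """Build one annotated anchor on the common (base-length) architecture.

    Anchors use canonical NPA boxes, a fixed filter draw and base loop lengths
    so all anchors share one coordinate frame.
    """
    from mipscan.anchor_align import ReferenceAnnotation

    template = make_subfamily_template(label)
    spec = replace(
        template,
        loop_lengths=dict(BASE_LOOP_LENGTHS),
        npa_b_sub_rate=0.0,
        npa_e_sub_rate=0.0,
        background_mutation_rate=0.0,
    )
    rng = _stable_rng("mip-anchor", ref_id)
    seq, truth = generate_sequence(spec, rng, seq_id=ref_id)
    spans = spec.segment_spans()
    arr_positions = {
        "TM2": spans["TM2"][0] + ARR_TM2_OFFSET,
        "TM5": spans["TM5"][0] + ARR_TM5_OFFSET,
        "LE1": spans["LE"][0] + LE1_OFFSET,
        "LE2": spans["LE"][0] + MOTIF_OFFSET,
    }
    interface_positions = tuple(
        spans[name][0] + off
        for name in ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6")
        for off in INTERFACE_OFFSETS[name]
    )
    seq = ProteinSequence(id=ref_id, residues=seq.residues, description=description)
    return ReferenceAnnotation(
        ref_id=ref_id,
        sequence=seq,
        tm_spans=truth.tm_spans,
        npa_b_pos=spans["LB"][0] + NPA_B_OFFSET,
        npa_e_pos=spans["LE"][0] + NPA_E_OFFSET,
        arr_positions=arr_positions,
        interface_positions=interface_positions,
        loop_e_motif_span=(spans["LE"][0] + MOTIF_OFFSET, spans["LE"][0] + MOTIF_OFFSET + 6),
    )


def default_anchors():
    """The three shipped anchors, rebuilt from the generator architecture."""
    return [build_anchor(rid, label, desc) for rid, label, desc in ANCHOR_DEFS]


def exemplar_sequences(seed: int = 929) -> Tuple[List[ProteinSequence], Dict[str, str]]:
    """One labeled exemplar per subfamily, for tree-based clade labeling."""
    records: List[ProteinSequence] = []
    labels: Dict[str, str] = {}
    for li, label in enumerate(SUBFAMILY_LABELS):
        spec = make_subfamily_template(label)
        rng = np.random.default_rng([seed, li])
        seq_id = f"exemplar|{label}"
        seq, _ = generate_sequence(spec, rng, seq_id=seq_id)
        records.append(seq)
        labels[seq_id] = label
    return records, labels
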