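"""Rule-based filter matching combined with tree clade assignment.

The rule table encodes the observed Ar/R filter residue sets per subfamily as
data (data/rules.json); classification combines the rule candidates with the
clade label from the bootstrapped NJ tree.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from mipscan.features import FeatureVector
from mipscan.io_core import ProteinSequence

SUBFAMILY_ORDER = (
    "AQP", "Fps1-like", "Yfl054-like", "alpha", "beta",
    "gamma1", "gamma2", "delta", "XIP", "SIP-like",
)

CONFIDENCE_LEVELS = ("rule+tree", "tree-only", "rule-only", "none")


@dataclass(frozen=True)
class SubfamilyRule:
    """Allowed residue sets at TM2/TM5/LE1/LE2 plus auxiliary predicates."""

    label: str
    tm2: frozenset
    tm5: frozenset
    le1: frozenset
    le2: frozenset
    require_non_arg_le2: bool = False
    max_mw_da: Optional[float] = None

    def matches(self, fv: FeatureVector) -> bool:
        arr = fv.arr
        for residue, allowed in (
            (arr.tm2, self.tm2), (arr.tm5, self.tm5),
            (arr.le1, self.le1), (arr.le2, self.le2),
        ):
            if residue is None or residue not in allowed:
                return False
        if self.require_non_arg_le2 and arr.le2 == "R":
            return False
        if self.max_mw_da is not None and not (fv.mw < self.max_mw_da):
            return False
        return True


@dataclass
class RuleTable:
    rules: Dict[str, SubfamilyRule]

    @staticmethod
    def from_dict(payload: dict, section: str = "fungal") -> "RuleTable":
        rules = {}
        for label, row in payload[section].items():
            rules[label] = SubfamilyRule(
                label=label,
                tm2=frozenset(row["TM2"]),
                tm5=frozenset(row["TM5"]),
                le1=frozenset(row["LE1"]),
                le2=frozenset(row["LE2"]),
                require_non_arg_le2=bool(row.get("require_non_arg_le2", False)),
                max_mw_da=row.get("max_mw_da"),
            )
        return RuleTable(rules=rules)

    @staticmethod
    def load(path=None, section: str = "fungal") -> "RuleTable":
        if path is None:
            text = resources.files("mipscan").joinpath("data/rules.json").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return RuleTable.from_dict(json.loads(text), section=section)


@dataclass(frozen=True)
class SubfamilyCall:
    """Final classification with its evidence trail."""

    seq_id: str
    label: str
    confidence: str
    rule_candidates: Tuple[str, ...]
    clade_label: str
    evidence: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.label == "unclassified") != (self.confidence == "none"):
            raise ValueError("label 'unclassified' iff confidence 'none'")


def rule_classify(fv: FeatureVector, rules: RuleTable) -> List[str]:
    """All subfamilies whose residue sets contain the observed filter.

    A filter position that could not be mapped (None) matches nothing, so any
    incomplete filter yields no candidates.
    """
    order = [label for label in SUBFAMILY_ORDER if label in rules.rules]
    order += [label for label in rules.rules if label not in order]
    return [label for label in order if rules.rules[label].matches(fv)]


def combine_calls(
    seq_id: str,
    rule_candidates: Sequence[str],
    clade_label: str = "unclassified",
) -> SubfamilyCall:
    """Merge rule candidates with the tree clade label.

    The clade label wins when present; confidence is rule+tree when it is also
    a rule candidate. Without a clade, a unique rule candidate gives a
    rule-only call; anything else is unclassified.
    """
    candidates = tuple(rule_candidates)
    evidence = [f"rule:{c}" for c in candidates]
    if clade_label != "unclassified":
        evidence.append(f"clade:{clade_label}")
        confidence = "rule+tree" if clade_label in candidates else "tree-only"
        return SubfamilyCall(seq_id, clade_label, confidence, candidates, clade_label, tuple(evidence))
    if len(candidates) == 1:
        return SubfamilyCall(seq_id, candidates[0], "rule-only", candidates, clade_label, tuple(evidence))
    return SubfamilyCall(seq_id, "unclassified", "none", candidates, clade_label, tuple(evidence))


def _residue_set_summary(values: Sequence[Optional[str]]) -> str:
    counts: Dict[str, int] = {}
    for v in values:
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return "/".join(f"{aa}:{n}" for aa, n in ordered)


def summarize_group(
    calls: Sequence[SubfamilyCall],
    fvs: Dict[str, FeatureVector],
) -> pd.DataFrame:
    """Per-subfamily summary: counts, filter residue sets, NPA substitution %,
    mean loop-D metrics, mean pI and MW.

    The NPA substitution percentage counts members with at least one
    substituted box and is rounded to one decimal. Empty subfamilies are
    omitted; row order follows the canonical subfamily order.
    """
    groups: Dict[str, List[FeatureVector]] = {}
    for call in calls:
        if call.label == "unclassified":
            continue
        groups.setdefault(call.label, []).append(fvs[call.seq_id])
    rows = []
    order = [label for label in SUBFAMILY_ORDER if label in groups]
    order += sorted(set(groups) - set(order))
    for label in order:
        members = groups[label]
        n = len(members)
        n_sub = sum(1 for fv in members if not (fv.npa_b.canonical and fv.npa_e.canonical))
        rows.append(
            {
                "subfamily": label,
                "n": n,
                "TM2": _residue_set_summary([fv.arr.tm2 for fv in members]),
                "TM5": _residue_set_summary([fv.arr.tm5 for fv in members]),
                "LE1": _residue_set_summary([fv.arr.le1 for fv in members]),
                "LE2": _residue_set_summary([fv.arr.le2 for fv in members]),
                "npa_substitution_pct": round(100.0 * n_sub / n, 1),
                "mean_loop_d_length": round(
                    float(np.mean([fv.loop_d_length for fv in members if fv.loop_d_length is not None])), 2
                ) if any(fv.loop_d_length is not None for fv in members) else math.nan,
                "mean_loop_d_charged": round(
                    float(np.mean([fv.loop_d_charged for fv in members if fv.loop_d_charged is not None])), 2
                ) if any(fv.loop_d_charged is not None for fv in members) else math.nan,
                "mean_pI": round(float(np.mean([fv.pI for fv in members])), 2),
                "mean_mw": round(float(np.mean([fv.mw for fv in members])), 1),
            }
        )
    return pd.DataFrame(rows)


def group_identity_stats(
    groups: Dict[str, Sequence[ProteinSequence]],
    **align_kwargs,
) -> pd.DataFrame:
    """Mean pairwise identity/similarity within and between groups.

    Rows: group_a, group_b (group_a == group_b for intra-group statistics),
    n_pairs, identity_pct, similarity_pct. Singleton groups get NA intra rows.
    """
    from mipscan.anchor_align import global_align

    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                members = list(groups[ga])
                pairs = list(itertools.combinations(members, 2))
            else:
                pairs = list(itertools.product(groups[ga], groups[gb]))
            if not pairs:
                rows.append(
                    {"group_a": ga, "group_b": gb, "n_pairs": 0,
                     "identity_pct": math.nan, "similarity_pct": math.nan}
                )
                continue
            idents, simils = [], []
            for a, b in pairs:
                aln = global_align(a, b, **align_kwargs)
                idents.append(aln.identity)
                simils.append(aln.similarity)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "n_pairs": len(pairs),
                    "identity_pct": round(100.0 * float(np.mean(idents)), 1),
                    "similarity_pct": round(100.0 * float(np.mean(simils)), 1),
                }
            )
    return pd.DataFrame(rows)
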