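"""End-to-end orchestration of the scan / tree / classify stages."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

import mipscan
from mipscan.anchor_align import ReferenceAnnotation, choose_reference, load_default_references
from mipscan.classify import RuleTable, SubfamilyCall, combine_calls, rule_classify, summarize_group
from mipscan.features import (
    FeatureError,
    FeatureVector,
    compute_mw,
    compute_pi,
    detect_loop_e_motif,
    extract_arr_filter,
    interface_conservation,
    locate_npa_boxes,
    loop_d_metrics,
    validate_mip,
)
from mipscan.io_core import ProteinSequence, dedup_sequences
from mipscan.phylo import (
    PhyloError,
    Tree,
    assign_clades,
    bootstrap_support,
    majority_rule_collapse,
    project_to_anchor,
)
from mipscan.synthetic import exemplar_sequences
from mipscan.topology import predict_topology

logger = logging.getLogger("mipscan")


@dataclass
class RunConfig:
    """Thresholds and knobs shared by the pipeline stages."""

    seed: int = 0
    dedup_threshold: Optional[float] = None  # None disables redundancy removal
    tm_window: int = 19
    # calibrated for the synthetic architecture; predict_topology itself
    # defaults to the classical 1.6 cutoff
    tm_threshold: float = 1.0
    tm_min_len: int = 15
    tm_max_len: int = 30
    min_conserved: int = 9
    bootstrap_reps: int = 100
    support_threshold: float = 50.0
    pka_set: str = "bjellqvist"

    def validate(self) -> None:
        if self.dedup_threshold is not None and not (0 < self.dedup_threshold <= 1):
            raise ValueError("dedup_threshold must be in (0, 1]")
        if self.tm_window % 2 == 0:
            raise ValueError("tm_window must be odd")
        if not (0 <= self.min_conserved <= 17):
            raise ValueError("min_conserved must be in [0, 17]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def scan_sequence(
    seq: ProteinSequence,
    refs: Sequence[ReferenceAnnotation],
    config: RunConfig,
) -> FeatureVector:
    """Compute the full feature vector (plus MIP validation) for one sequence."""
    ref, aln = choose_reference(seq, refs)
    try:
        npa_b, npa_e = locate_npa_boxes(seq, aln, ref)
    except FeatureError:
        from mipscan.features import NpaBox

        npa_b = NpaBox.from_triplet("B", "XXX")
        npa_e = NpaBox.from_triplet("E", "XXX")
    arr = extract_arr_filter(seq, aln, ref)
    conserved = interface_conservation(seq, aln, ref)

    topo = predict_topology(
        seq,
        threshold=config.tm_threshold,
        min_len=config.tm_min_len,
        max_len=config.tm_max_len,
        window=config.tm_window,
    )
    if topo.n_tm >= 5:
        ld_len, ld_charged = loop_d_metrics(seq, topo)
    else:
        ld_len = ld_charged = None

    # loop-E motif window: 6 residues after the mapped loop-E box
    from mipscan.anchor_align import map_positions

    e_end = map_positions(aln, [ref.npa_e_pos + 2])[0]
    if e_end is not None:
        motif_class, salt_bridge = detect_loop_e_motif(seq, (e_end + 1, e_end + 7))
    else:
        motif_class, salt_bridge = "none", False

    fv = FeatureVector(
        seq_id=seq.id,
        length=len(seq),
        pI=round(compute_pi(seq, pka_set=config.pka_set), 2),
        mw=round(compute_mw(seq, on_x="estimate"), 1),
        npa_b=npa_b,
        npa_e=npa_e,
        arr=arr,
        loop_d_length=ld_len,
        loop_d_charged=ld_charged,
        loop_e_motif_class=motif_class,
        salt_bridge=salt_bridge,
        interface_conserved=conserved,
        ref_id=ref.ref_id,
        anchor_identity=round(aln.identity, 4),
    )
    is_mip, reasons = validate_mip(seq, fv, topo, min_conserved=config.min_conserved)
    fv.is_mip = is_mip
    fv.reasons = reasons
    return fv


def features_to_frame(fvs: Sequence[FeatureVector]) -> pd.DataFrame:
    rows = []
    for fv in fvs:
        rows.append(
            {
                "id": fv.seq_id,
                "length": fv.length,
                "pI": fv.pI,
                "mw": fv.mw,
                "npa_b": fv.npa_b.triplet,
                "npa_e": fv.npa_e.triplet,
                "npa_b_canonical": fv.npa_b.canonical,
                "npa_e_canonical": fv.npa_e.canonical,
                "arr_tm2": fv.arr.tm2 or "-",
                "arr_tm5": fv.arr.tm5 or "-",
                "arr_le1": fv.arr.le1 or "-",
                "arr_le2": fv.arr.le2 or "-",
                "arr_complete": fv.arr.complete,
                "loop_d_length": fv.loop_d_length,
                "loop_d_charged": fv.loop_d_charged,
                "loop_e_motif_class": fv.loop_e_motif_class,
                "salt_bridge": fv.salt_bridge,
                "interface_conserved": fv.interface_conserved,
                "is_mip": fv.is_mip,
                "reasons": ";".join(fv.reasons),
                "ref_id": fv.ref_id,
                "anchor_identity": fv.anchor_identity,
            }
        )
    return pd.DataFrame(rows)


def run_scan(
    seqs: Sequence[ProteinSequence],
    config: Optional[RunConfig] = None,
    refs: Optional[Sequence[ReferenceAnnotation]] = None,
) -> Tuple[pd.DataFrame, List[FeatureVector]]:
    """Feature table + validation verdicts for every input sequence."""
    config = config or RunConfig()
    config.validate()
    refs = list(refs) if refs is not None else load_default_references()
    fvs = [scan_sequence(seq, refs, config) for seq in seqs]
    n_valid = sum(1 for fv in fvs if fv.is_mip)
    logger.info("scanned %d sequences; %d pass MIP validation", len(fvs), n_valid)
    return features_to_frame(fvs), fvs


def run_classify(
    seqs: Sequence[ProteinSequence],
    config: Optional[RunConfig] = None,
    refs: Optional[Sequence[ReferenceAnnotation]] = None,
    labeled_refs: Optional[Tuple[Sequence[ProteinSequence], Dict[str, str]]] = None,
) -> Dict[str, object]:
    """Scan, build the bootstrapped NJ tree, assign clades, emit calls + summary.

    ``labeled_refs`` is (sequences, id->subfamily); when omitted the built-in
    per-subfamily exemplars are used. With fewer than 3 valid MIPs the
    phylogeny is skipped and rule-only calls are emitted.
    """
    config = config or RunConfig()
    config.validate()
    refs = list(refs) if refs is not None else load_default_references()
    rules = RuleTable.load()

    seqs = list(seqs)
    removed_map: Dict[str, str] = {}
    if config.dedup_threshold is not None and seqs:
        seqs, removed_map = dedup_sequences(seqs, config.dedup_threshold)
        logger.info("dedup removed %d redundant sequences", len(removed_map))

    feature_df, fvs = run_scan(seqs, config, refs)
    fv_by_id = {fv.seq_id: fv for fv in fvs}
    valid = [seq for seq, fv in zip(seqs, fvs) if fv.is_mip]

    if labeled_refs is None:
        exemplars, exemplar_labels = exemplar_sequences()
    else:
        exemplars, exemplar_labels = list(labeled_refs[0]), dict(labeled_refs[1])

    tree: Optional[Tree] = None
    collapsed: Optional[Tree] = None
    clades: Dict[str, str] = {}
    if len(valid) >= 3:
        tree_input = list(valid) + [e for e in exemplars if e.id not in {s.id for s in valid}]
        alignment = project_to_anchor(tree_input, refs)
        try:
            tree = bootstrap_support(alignment, n_reps=config.bootstrap_reps, seed=config.seed)
            collapsed = majority_rule_collapse(tree, threshold=config.support_threshold)
            clades = assign_clades(collapsed, exemplar_labels, support_threshold=config.support_threshold)
        except PhyloError as exc:
            logger.warning("phylogeny skipped: %s", exc)
    else:
        logger.warning("fewer than 3 valid MIPs; phylogeny skipped, rule-only calls emitted")

    calls: List[SubfamilyCall] = []
    for seq, fv in zip(seqs, fvs):
        candidates = rule_classify(fv, rules) if fv.is_mip else []
        clade = clades.get(seq.id, "unclassified") if fv.is_mip else "unclassified"
        calls.append(combine_calls(seq.id, candidates, clade))
    # propagate calls to dedup-removed duplicates
    call_by_id = {c.seq_id: c for c in calls}
    for removed_id, kept_id in removed_map.items():
        kept = call_by_id[kept_id]
        calls.append(
            SubfamilyCall(
                seq_id=removed_id,
                label=kept.label,
                confidence=kept.confidence,
                rule_candidates=kept.rule_candidates,
                clade_label=kept.clade_label,
                evidence=kept.evidence + (f"duplicate-of:{kept_id}",),
            )
        )

    calls_df = pd.DataFrame(
        {
            "id": [c.seq_id for c in calls],
            "label": [c.label for c in calls],
            "confidence": [c.confidence for c in calls],
            "rule_candidates": [";".join(c.rule_candidates) for c in calls],
            "clade_label": [c.clade_label for c in calls],
            "evidence": [";".join(c.evidence) for c in calls],
        }
    )
    summary_df = summarize_group([c for c in calls if c.seq_id in fv_by_id], fv_by_id)
    return {
        "features": feature_df,
        "feature_vectors": fvs,
        "calls": calls,
        "calls_df": calls_df,
        "summary": summary_df,
        "tree": tree,
        "collapsed_tree": collapsed,
        "clades": clades,
        "removed_map": removed_map,
    }


def write_manifest(path, config: RunConfig, extra: Optional[dict] = None) -> None:
    payload = {
        "package": "mipscan",
        "version": mipscan.__version__,
        "config": asdict(config),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
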