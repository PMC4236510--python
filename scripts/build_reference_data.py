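"""Regenerate src/mipscan/data/references.json.

The three anchors play the roles of the water-channel, glycerol-channel and
small-channel structural templates used for position mapping. Real deposited
template structures are not redistributable here, so the anchors are canonical
consensus sequences built deterministically from the package's hourglass
architecture, with the NPA boxes, Ar/R filter positions, the 17 helix-helix
interface positions and the loop-E motif span annotated exactly. The SIP-like
molecular-weight rule threshold is calibrated from generator output at the
same time.

Run from the repository root:  python scripts/build_reference_data.py
"""

import json
from pathlib import Path

from mipscan.features import compute_mw
from mipscan.synthetic import ANCHOR_DEFS, SUBFAMILY_LABELS, build_anchor, generate_dataset

OUT = Path(__file__).resolve().parents[1] / "src" / "mipscan" / "data" / "references.json"


def main() -> None:
    refs = []
    for ref_id, label, desc in ANCHOR_DEFS:
        ann = build_anchor(ref_id, label, desc)
        refs.append(
            {
                "ref_id": ann.ref_id,
                "description": ann.sequence.description,
                "sequence": ann.sequence.residues,
                "tm_spans": [list(s) for s in ann.tm_spans],
                "npa_b_pos": ann.npa_b_pos,
                "npa_e_pos": ann.npa_e_pos,
                "arr_positions": ann.arr_positions,
                "interface_positions": list(ann.interface_positions),
                "loop_e_motif_span": list(ann.loop_e_motif_span),
            }
        )
    payload = {
        "version": 1,
        "provenance": (
            "Synthetic consensus anchors derived from the package's hourglass "
            "architecture (see mipscan.synthetic.build_anchor); they stand in "
            "for the AQP1/GlpF/AQPM structural templates for position mapping."
        ),
        "references": refs,
    }
    OUT.write_text(json.dumps(payload, indent=1) + "\n")
    print(f"wrote {OUT}")

    # report per-subfamily molecular weights to sanity-check the SIP-like cutoff
    seqs, truth = generate_dataset(SUBFAMILY_LABELS, 5, seed=1)
    for label in SUBFAMILY_LABELS:
        mws = [compute_mw(s) for s in seqs if s.id.startswith(label + "_")]
        print(f"{label:>12}: mean MW {sum(mws) / len(mws):9.1f} Da")


if __name__ == "__main__":
    main()
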