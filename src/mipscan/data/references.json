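{
 "version": 1,
 "provenance": "Synthetic consensus anchors derived from the package's hourglass architecture (see mipscan.synthetic.build_anchor); they stand in for the AQP1/GlpF/AQPM structural templates for position mapping.",
 "references": [
  {
   "ref_id": "AQP-anchor",
   "description": "water-channel-type anchor (AQP1/1J4N role)",
   "sequence": "EEQPDKKRGKGGLVLIGVLIVLAVIILLVIALLTQKRESTSNQIIIIAVLIVIAILLIFVVGVIPGENPADRKHEHPQVLVIAIVLLIAVLLLIIVGLIQSGRDKHQQSSRPGHRIVIIAIIVVLAVVIILVIAILSEDRNTNRHRQTVIIIGIILIIAVIILAVVALIHSAESNPARSKGPCKTGNHRVILIGVVVLIAVVIILLVLLLEEKKRRRHTPTG",
   "tm_spans": [
    [
     12,
     33
    ],
    [
     43,
     64
    ],
    [
     78,
     99
    ],
    [
     115,
     136
    ],
    [
     148,
     169
    ],
    [
     189,
     210
    ]
   ],
   "npa_b_pos": 67,
   "npa_e_pos": 174,
   "arr_positions": {
    "TM2": 58,
    "TM5": 163,
    "LE1": 171,
    "LE2": 177
   },
   "interface_positions": [
    16,
    22,
    30,
    47,
    53,
    61,
    82,
    88,
    96,
    119,
    125,
    133,
    152,
    158,
    166,
    193,
    199
   ],
   "loop_e_motif_span": [
    177,
    183
   ]
  },
  {
   "ref_id": "AQGP-anchor",
   "description": "glycerol-channel-type anchor (GlpF/1FX8 role)",
   "sequence": "EERRDKKRKKGGLVLIGVVVVLALIILVLVALITQTNENTSRDILIVALLLVIAILVIWLVGIIPGKNPADHDQEHPQLLVIAIVILVAIILLVIVGLLNSGEDKHQQSHRPGGRLIIVAIIVVLAIVIVVLVAILPEDRGTNNHQKDVIIVGVIVIIALIIVGIIAVIHSFEENPARDPGPRKNGSHEVILIGVIILIAVLIILLVLLLEEDKRRRRTHTG",
   "tm_spans": [
    [
     12,
     33
    ],
    [
     43,
     64
    ],
    [
     78,
     99
    ],
    [
     115,
     136
    ],
    [
     148,
     169
    ],
    [
     189,
     210
    ]
   ],
   "npa_b_pos": 67,
   "npa_e_pos": 174,
   "arr_positions": {
    "TM2": 58,
    "TM5": 163,
    "LE1": 171,
    "LE2": 177
   },
   "interface_positions": [
    16,
    22,
    30,
    47,
    53,
    61,
    82,
    88,
    96,
    119,
    125,
    133,
    152,
    158,
    166,
    193,
    199
   ],
   "loop_e_motif_span": [
    177,
    183
   ]
  },
  {
   "ref_id": "SIP-anchor",
   "description": "small-channel anchor (AQPM/2F2B role)",
   "sequence": "EERRDKTRKKEGLVIIGVVVVLALILLVLIALITETNENTSPDIVVVAILVVIAVIVIILIGVIPGNNPATGTQESPQVVVIAIVLLIAVVLLIIVGLINSGEEEHRQSNRKNHRIIIIALIVVLAVVIILVVAILKDDQGRDRKRQTVIIIGVIVIIAIIIVAVVAVIHSGSSNPALPPEQGKSGNHQVILIGVVIVLALVVLLVVLVVEHHKRNRHTHTG",
   "tm_spans": [
    [
     12,
     33
    ],
    [
     43,
     64
    ],
    [
     78,
     99
    ],
    [
     115,
     136
    ],
    [
     148,
     169
    ],
    [
     189,
     210
    ]
   ],
   "npa_b_pos": 67,
   "npa_e_pos": 174,
   "arr_positions": {
    "TM2": 58,
    "TM5": 163,
    "LE1": 171,
    "LE2": 177
   },
   "interface_positions": [
    16,
    22,
    30,
    47,
    53,
    61,
    82,
    88,
    96,
    119,
    125,
    133,
    152,
    158,
    166,
    193,
    199
   ],
   "loop_e_motif_span": [
    177,
    183
   ]
  }
 ]
}
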