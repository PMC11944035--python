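[
  {
    "kind": "state_cell",
    "scenario": "sm0g",
    "level": "C5C6",
    "metric": "volume",
    "printed": 2814.4,
    "note": "Printed volume disagrees with height x area = 5.2 x 542 = 2818.4 mm^3; the recomputed value is used internally and both are reported."
  },
  {
    "kind": "summary",
    "metric": "mean_compression_change_nbp1g_to_nbp0g_pct",
    "printed": -76.6,
    "note": "The source report's summary quotes an average compressive-force reduction of 76.6%; the mean of the six per-level changes is -75.6%. 76.6% is the C2-C3 value, not the mean."
  },
  {
    "kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "height", "level": "C2C3", "printed_pct": -0.4,
    "note": "No convention tried (relative change, ratio, swapped operands) reproduces the printed upright-0G vs neutral-0G geometry contrast block; recomputed values are reported alongside."
  },
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "height", "level": "C3C4", "printed_pct": -4.1, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "height", "level": "C4C5", "printed_pct": -5.1, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "height", "level": "C5C6", "printed_pct": -1.4, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "height", "level": "C6C7", "printed_pct": -8.3, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "height", "level": "C7T1", "printed_pct": -6.5, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "area", "level": "C2C3", "printed_pct": -1.1, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "area", "level": "C3C4", "printed_pct": -1.8, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "area", "level": "C4C5", "printed_pct": -3.3, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "area", "level": "C5C6", "printed_pct": -4.4, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "area", "level": "C6C7", "printed_pct": -1.4, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "area", "level": "C7T1", "printed_pct": -1.7, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "volume", "level": "C2C3", "printed_pct": -1.5, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "volume", "level": "C3C4", "printed_pct": -6.0, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "volume", "level": "C4C5", "printed_pct": -1.9, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "volume", "level": "C5C6", "printed_pct": -5.8, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "volume", "level": "C6C7", "printed_pct": -9.9, "note": "see height C2C3 entry"},
  {"kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "volume", "level": "C7T1", "printed_pct": -8.3, "note": "see height C2C3 entry"},
  {
    "kind": "contrast_cell", "scenario_ref": "nbp0g", "scenario_new": "sm0g", "metric": "ligament_force", "level": "LF", "printed_pct": 3.9,
    "note": "89.37/85.97 - 1 = 3.955% rounds to 4.0; the printed 3.9 looks truncated rather than rounded."
  },
  {
    "kind": "note",
    "metric": "shear_contrast_wording_nbp0g_vs_sm0g",
    "note": "The C6-C7 and C7-T1 shear contrasts are worded as 'percent of' but the printed 2011.1% and 1175.9% are exactly the relative changes (1.9-0.09)/0.09 and (3.7-0.29)/0.29; they are reproduced as percent-change cells, not flagged."
  },
  {
    "kind": "note",
    "metric": "muscle_force_table",
    "note": "Most upright/neutral 0G muscle-force entries are ~1e-5 N and below optimizer residual scale; the muscle table is excluded from reproduction."
  }
]
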