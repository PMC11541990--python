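{
  "description": "Published cross-tabulated counts from a flow-cytometry-screened Mayo Clinic MBL/CLL cohort (4632 individuals), used to recompute printed prevalence and screening fractions without access to individual-level data.",
  "group_sizes": {
    "none": 2971,
    "lc_mbl": 728,
    "hc_mbl": 332,
    "cll": 497,
    "sll": 104
  },
  "canonical_carriers": {
    "none": 4,
    "lc_mbl": 8,
    "hc_mbl": 173
  },
  "driver_screen_hc_vs_rest": {
    "tp": 190,
    "fn": 142,
    "tn": 3645,
    "fp": 54
  },
  "sex_chromosome_loss": {
    "loy_carriers": 325,
    "n_males": 2170,
    "lox_carriers": 41,
    "n_females": 2462
  },
  "mca_totals": {
    "n_individuals": 4632,
    "any_mca_carriers": 1213,
    "autosomal_mca_carriers": 912
  }
}
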