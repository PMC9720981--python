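{
  "description": "Canonical gated-subset dictionary. Every frequency is percent of its stated parent gate (as gated), never percent of lymphocytes. 'lymphocytes' is the absolute-count root supplied by the haematology lymphocyte count (1e9 cells/L).",
  "subsets": {
    "tcell_of_lymphs": {"parent": "lymphocytes", "markers": "CD3+", "label": "T cells (% of lymphocytes)"},
    "bcell_of_lymphs": {"parent": "lymphocytes", "markers": "CD19+", "label": "B cells (% of lymphocytes)"},
    "cd4_of_t": {"parent": "tcell_of_lymphs", "markers": "CD3+CD4+", "label": "CD4 T cells (% of T)"},
    "cd8_of_t": {"parent": "tcell_of_lymphs", "markers": "CD3+CD8+", "label": "CD8 T cells (% of T)"},
    "cd4_naive": {"parent": "cd4_of_t", "markers": "CD45RA+CCR7+", "group": "cd4_quartet", "label": "naive CD4"},
    "cd4_cm": {"parent": "cd4_of_t", "markers": "CD45RA-CCR7+", "group": "cd4_quartet", "label": "central memory CD4"},
    "cd4_em": {"parent": "cd4_of_t", "markers": "CD45RA-CCR7-", "group": "cd4_quartet", "label": "effector memory CD4"},
    "cd4_emra": {"parent": "cd4_of_t", "markers": "CD45RA+CCR7-", "group": "cd4_quartet", "label": "EMRA CD4"},
    "cd8_naive": {"parent": "cd8_of_t", "markers": "CD45RA+CCR7+", "group": "cd8_quartet", "label": "naive CD8"},
    "cd8_cm": {"parent": "cd8_of_t", "markers": "CD45RA-CCR7+", "group": "cd8_quartet", "label": "central memory CD8"},
    "cd8_em": {"parent": "cd8_of_t", "markers": "CD45RA-CCR7-", "group": "cd8_quartet", "label": "effector memory CD8"},
    "cd8_emra": {"parent": "cd8_of_t", "markers": "CD45RA+CCR7-", "group": "cd8_quartet", "label": "EMRA CD8"},
    "cd4_cd28neg": {"parent": "cd4_of_t", "markers": "CD28-", "label": "CD28- CD4"},
    "cd4_cd57pos": {"parent": "cd4_of_t", "markers": "CD57+", "label": "CD57+ CD4"},
    "cd4_senescent": {"parent": "cd4_of_t", "markers": "CD28-CD57+", "intersection_of": ["cd4_cd28neg", "cd4_cd57pos"], "label": "senescent CD4"},
    "cd8_cd28neg": {"parent": "cd8_of_t", "markers": "CD28-", "label": "CD28- CD8"},
    "cd8_cd57pos": {"parent": "cd8_of_t", "markers": "CD57+", "label": "CD57+ CD8"},
    "cd8_senescent": {"parent": "cd8_of_t", "markers": "CD28-CD57+", "intersection_of": ["cd8_cd28neg", "cd8_cd57pos"], "label": "senescent CD8"},
    "rte_of_naive_cd4": {"parent": "cd4_naive", "markers": "PTK7+", "label": "recent thymic emigrants (% of naive CD4)"},
    "treg_of_cd4": {"parent": "cd4_of_t", "markers": "CD25+Foxp3+", "label": "regulatory T cells (% of CD4)"},
    "b_naive": {"parent": "bcell_of_lymphs", "markers": "CD27-IgD+", "group": "b_subsets", "label": "naive B"},
    "b_switched_mem": {"parent": "bcell_of_lymphs", "markers": "CD27+IgD-", "group": "b_subsets", "label": "switched memory B"},
    "b_unswitched_mem": {"parent": "bcell_of_lymphs", "markers": "CD27+IgD+", "group": "b_subsets", "label": "unswitched memory B"},
    "breg_of_b": {"parent": "bcell_of_lymphs", "markers": "CD24hiCD38hi", "label": "regulatory B"}
  },
  "exhaustive_groups": ["cd4_quartet", "cd8_quartet"],
  "bounded_sibling_groups": {
    "t_lineage_split": ["cd4_of_t", "cd8_of_t"],
    "lymph_split": ["tcell_of_lymphs", "bcell_of_lymphs"],
    "b_subsets": ["b_naive", "b_switched_mem", "b_unswitched_mem"]
  }
}
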