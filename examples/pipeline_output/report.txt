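n_records_curated = 2000
n_variables_curated = 50
rf_n_selected = 13
lasso_n_selected = 13
rf_n_significant = 12
lasso_n_significant = 12
rf_n_edges = 66
lasso_n_edges = 66
rf_n_communities = 2
lasso_n_communities = 2
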