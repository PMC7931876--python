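{
 "artifacts": {
  "cohort": {
   "path": "cohort.csv",
   "sha256": "efbba954ae01043f2460bcb171ad9fc87fd5d3f282e184e181d1f935048bd34f"
  },
  "communities_lasso": {
   "path": "communities_lasso.csv",
   "sha256": "46f7817d0a53e3938d7638d0dbedd5b10bb58fe06a4da8c293024715b132c71f"
  },
  "communities_rf": {
   "path": "communities_rf.csv",
   "sha256": "46f7817d0a53e3938d7638d0dbedd5b10bb58fe06a4da8c293024715b132c71f"
  },
  "compare_arms": {
   "path": "compare_arms.json",
   "sha256": "9dd4144f8471a584a5f424ce94e1347e8dd1ec7bf0f5721f5542fe039b7fd3b1"
  },
  "curated": {
   "path": "curated.csv",
   "sha256": "f105e6a5c7832bac482910fb7f0c4fff00b509e3a5c6220b88fb4648e00fb42c"
  },
  "curation_ledger": {
   "path": "curation_ledger.csv",
   "sha256": "71b092876fd228ee0597e180f83aa30f5c7e00fb0d87a13cf4eaab3687e669a7"
  },
  "dendrogram_lasso": {
   "path": "dendrogram_lasso.csv",
   "sha256": "9712e215be46c85daabdfc2229a9a6ad84f773da214aa0c73a47f3ca9a83deaf"
  },
  "dendrogram_rf": {
   "path": "dendrogram_rf.csv",
   "sha256": "9712e215be46c85daabdfc2229a9a6ad84f773da214aa0c73a47f3ca9a83deaf"
  },
  "importances_rf": {
   "path": "importances_rf.csv",
   "sha256": "6b76adc01a3adfa309a3df126c850609d60d90f4b05d873610d63d292581eb5c"
  },
  "metrics_lasso": {
   "path": "metrics_lasso.json",
   "sha256": "4e63a3bd647485868b95afb3adb1ba574caa8a73c0d0a082283e34fe09b02b31"
  },
  "metrics_rf": {
   "path": "metrics_rf.json",
   "sha256": "b5754dcb6ab5ef1eec06f2be151262488e73afcd170aa379048bdf103f771d25"
  },
  "network_lasso": {
   "path": "network_lasso.graphml",
   "sha256": "d8da49cd6c15fabded1f17ed361cfb17c418f9a1809d2f9bf693ff94ec6587ac"
  },
  "network_lasso_edges": {
   "path": "network_lasso_edges.csv",
   "sha256": "0ac70e8c4dcbc07636cb22b8c4266edbe4807d6e918110fc66c9b72265fa6758"
  },
  "network_lasso_nodes": {
   "path": "network_lasso_nodes.csv",
   "sha256": "7a1617456dc9624a777b6e1433da2f7278991ecaebcdda167d0997328184d613"
  },
  "network_rf": {
   "path": "network_rf.graphml",
   "sha256": "cfede294a65826cc8852259d17b4f490b84e45f070a11cef704e8bf705fd34ef"
  },
  "network_rf_edges": {
   "path": "network_rf_edges.csv",
   "sha256": "2f1ea78d075415802ae0c01380bf648bc29ae926278f5f7f19183e14c5159307"
  },
  "network_rf_nodes": {
   "path": "network_rf_nodes.csv",
   "sha256": "7a1617456dc9624a777b6e1433da2f7278991ecaebcdda167d0997328184d613"
  },
  "scores_lasso": {
   "path": "scores_lasso.csv",
   "sha256": "bfdfbdc82766935dd1a85c39d6a99f2ec5ec8be2fad2546935ce6394f112d68b"
  },
  "scores_rf": {
   "path": "scores_rf.csv",
   "sha256": "bfdfbdc82766935dd1a85c39d6a99f2ec5ec8be2fad2546935ce6394f112d68b"
  },
  "selected_lasso": {
   "path": "selected_lasso.csv",
   "sha256": "4e5a4b7e5fffbb7657a5a8cedef60ef62f94947fc8c24a03a096117d70ae7416"
  },
  "selected_rf": {
   "path": "selected_rf.csv",
   "sha256": "4e5a4b7e5fffbb7657a5a8cedef60ef62f94947fc8c24a03a096117d70ae7416"
  }
 },
 "config": {
  "alpha": 0.05,
  "cohort_path": null,
  "cohort_spec": {
   "blocks": [
    {
     "baseline_prevalence": 0.3,
     "n_features": 6,
     "name": "cardio",
     "within_block_association": 8.0
    },
    {
     "baseline_prevalence": 0.25,
     "n_features": 6,
     "name": "renal",
     "within_block_association": 8.0
    }
   ],
   "missing_rate": 0.0,
   "n_noise_features": 30,
   "n_patients": 2000,
   "n_redundant": 2,
   "outcome_coefficients": {
    "cardio_1": 0.6,
    "cardio_2": 0.6,
    "cardio_3": 0.6,
    "cardio_4": 0.6,
    "cardio_5": 0.6,
    "cardio_6": 0.6,
    "renal_1": 0.6,
    "renal_2": 0.6,
    "renal_3": 0.6,
    "renal_4": 0.6,
    "renal_5": 0.6,
    "renal_6": 0.6
   },
   "outcome_intercept": -2.5,
   "seed": 0
  },
  "curation": {
   "bmi_breaks": [
    18.5,
    25.0,
    30.0
   ],
   "dichotomize_rules": {},
   "exclude_outcome_labels": [],
   "exclude_variables": [],
   "max_missing_fraction": 0.5,
   "min_age": 17.0
  },
  "methods": [
   "rf",
   "lasso"
  ],
  "n_trees": 300,
  "network": {
   "B": 999,
   "alpha": 0.05,
   "base": "nats",
   "cases_only": true,
   "correction": "fdr_bh",
   "min_patients": 15
  },
  "plan": {
   "cv_folds": 10,
   "seed": 0,
   "train_fraction": 0.7
  },
  "seed": 2024,
  "weighted": true
 },
 "stage_seeds": {
  "communities": 1408573266,
  "curate": 936494452,
  "network": 1992480867,
  "score": 1369693403,
  "select": 172152025,
  "simulate": 1378679599
 }
}
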