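{
  "seed": 42,
  "outdir": "scratch/pipeline_out",
  "thresholds": {"rarefaction_depth": 20000},
  "simulation": {
    "genomes": {
      "ancestor": {"id": "ancA", "length": 60000, "gc_target": 0.4},
      "children": [
        {"id": "refA", "length": 60000, "gc_target": 0.4, "divergence_from_parent": 0.0},
        {"id": "refB", "length": 60000, "gc_target": 0.4, "divergence_from_parent": 0.15},
        {"id": "strainA", "length": 60000, "gc_target": 0.4, "divergence_from_parent": 0.005, "parent": "refA"},
        {"id": "novel1", "length": 60000, "gc_target": 0.4, "divergence_from_parent": 0.15, "parent": "refA"},
        {"id": "novel2", "length": 60000, "gc_target": 0.4, "divergence_from_parent": 0.12, "parent": "refB"}
      ]
    },
    "references": ["refA", "refB"],
    "reference_species": {"refA": "Species alpha", "refB": "Species beta"},
    "contigs": [
      {"genome": "strainA", "n_contigs": 20, "coverage_mean": 50, "coverage_cv": 0.05, "min_len": 1500, "seed_offset": 11},
      {"genome": "novel1", "n_contigs": 20, "coverage_mean": 30, "coverage_cv": 0.05, "min_len": 1500, "seed_offset": 12},
      {"genome": "novel2", "n_contigs": 20, "coverage_mean": 120, "coverage_cv": 0.05, "min_len": 1500, "seed_offset": 13}
    ],
    "cohort": {"n_patients": 12, "depth_per_sample": 20000},
    "mlst": {
      "samples": [
        {"id": "S1", "st": 1, "seed_offset": 0},
        {"id": "S2", "st": 1, "seed_offset": 1}
      ]
    },
    "genes": {"n_genes": 25, "gene_len": 800, "spacing": 200}
  }
}
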