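{
  "method": "sgek-diis",
  "converged": false,
  "iterations": 1,
  "final_energy": -1.1257575587419755,
  "trace_path": "gekscf_out/trace_sgek-diis.csv"
}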