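# config: {"e_tol": 1e-09, "expansion_method": "diis", "first_step_norm": 0.3, "fock_tol": 0.00015, "hessian_floor": 0.025, "loosen_angle": 5.0, "loosen_factor": 1.618033988749895, "max_history": 20, "max_iter": 1, "micro_max": 200, "mitigation": true, "mu_offset": 10.0, "rgdiis_step_norm": 0.5, "seed": 0, "step_tol": 0.001, "tighten_angle": 20.0, "variance_coefficient": 0.3}
iter,energy,d_energy,g_max,step_norm,variance,f_L,K,method
0,-1.074106903363881,,0.17013602320381735,0.13131165010048504,0.0,1.0,0,sgek-diis
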