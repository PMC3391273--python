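# Full two-structure comparison of NpAS (1G5A) vs DgAS (prepared 3UCQ).
# Place the PDB files under data/structures/ first; see README.
structure_a: data/structures/1G5A.pdb
structure_b: data/structures/3UCQ.pdb
domains_a: examples/domains_1g5a.cfg
domains_b: examples/domains_3ucq.cfg
label_a: NpAS
label_b: DgAS
out_dir: comparison_out
seed: 0
run_unfold: false   # enable for the (hours-long) unfolding stage
replicates: 5
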