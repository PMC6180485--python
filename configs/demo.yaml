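# Demo run: desk-scale synthetic study at the default study conditions.
# wt carries a 50 nt post-PAS readthrough decay, dis2d 400 nt; spike-in
# cells at 15% of fission-yeast cells; 300 genes; 2e5 reads per sample.
seed: 1
outdir: demo_run
simulation: {}
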