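# Reference two-population simulation profile for `selsig simulate --profile`.
# Omitted fields fall back to the SimParams defaults (18 x 40 Mb autosomes,
# ~20,000 SNPs, three 2 Mb sweeps per population auto-placed on chromosomes
# 1-6). All values here restate those defaults explicitly for visibility.
n_pop1: 50
n_pop2: 50
n_chrom: 18
chrom_len: 40000000
snp_density: 2.78e-5
f_background: 0.03
f_sweep: 0.35
sweep_freq_push: 3.0
missing_rate: 0.02
seed: 0
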