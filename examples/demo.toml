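# Desk-scale demo configuration: synthetic cohort end to end.
# Every analysis threshold shown here at its default value.

seed = 1

[simulate]
n_chromosomes = 5
snps_per_chromosome = 400
chromosome_length_bp = 80000000
n_qtl = 3
qtl_effect_sd = 0.45
missing_rate = 0.01

[qc]
ind_call_rate = 0.90
snp_call_rate = 0.90
het_excess_max = 0.499
maf_min = 0.00001

[h2]
enabled = true
tol = 1e-6

[gwas]
tiers = [0.01, 0.05, 0.10]
estimate_dispersion = false

[filters]
maf_min = 0.2
chi2_alpha = 0.05
polarity_min = 0.3

[rf]
n_forests = 10
n_trees = 25

[ld]
window_bp = 2000000
r2_min = 0.2
strong_ld_min = 0.2
max_significant_snps = 20
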