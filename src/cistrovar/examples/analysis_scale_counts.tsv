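name	count
consensus_loci	23409
lead_snps	10432
ld_snps	181050
snps_in_universe	191482
traits_in_universe	930
snps_under_peaks	574
distinct_scored_under_peaks	572
traits_under_peaks	211
significant_trait_snps	42
loci_with_dr3_motif	8897
snps_in_dr3_motif	15
shared_loci_with_second_factor	5635
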