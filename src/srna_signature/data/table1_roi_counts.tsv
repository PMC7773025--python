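# Sample roster of the sequencing experiment: total library sizes and
# reads of each size class (20-25 nt) mapping to the target region of
# interest. The reads_matching_roi column is blank in the source table
# and is kept blank here; see SizeClassTable.roi_row_sum for the two
# possible readings.
sample	condition	total_reads	reads_matching_roi	len20	len21	len22	len23	len24	len25
16C-ds_1	target_ds	7186316		208	194	186	162	152	156
16C-ds_2	target_ds	7511064		299	260	276	214	229	204
16C-ds_3	target_ds	7375715		230	222	202	179	127	122
WT-ds_1	wildtype_ds	8363721		300	314	275	214	239	201
WT-ds_2	wildtype_ds	8824820		237	234	246	209	171	164
WT-ds_3	wildtype_ds	8434532		249	220	209	193	182	148
16C-w	target_water	7718149		9	14	37	5	11	10
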