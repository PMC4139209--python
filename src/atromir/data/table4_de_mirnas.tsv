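# Partial transcription of the differential-expression summary for the two focal
# miRNAs. The full per-condition fold-change table is printed only as an image in the
# source; only regulation calls recoverable from the running text are recorded here
# (fold-change thresholds for calls: down < 0.8, up > 1.2, ANOVA p <= 0.05).
mirna	condition	direction
miR-206	Den7	up
miR-206	Den14	up
miR-206	STV48	up
miR-206	STZ	up
miR-21	Den7	up
miR-21	Den14	up
miR-21	STZ	up
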