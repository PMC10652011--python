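MSI_stem_like_progenitor	v1 MSI CRC IFNG+CD8 co-expression module; SLAMF6 inferred	TCF7	IL2	CD28	SLAMF6
MSI_inflamed_follicular_like	v1 MSI CRC IFNG+CD8 co-expression module	CXCR5	BCL6	ICOS
MSI_long_term_immunosurveillance	v1 MSI CRC IFNG+CD8 co-expression module	EOMES	TBX21	PRDM1	KLRK1	KLRG1
MSI_tumor_reactive_exhaustion	v1 MSI CRC IFNG+CD8 co-expression module; JAK3 inferred	IFNG	LAG3	PDCD1	CTLA4	TIGIT	ENTPD1	HAVCR2	CXCL13	NFATC2	JAK3
MSI_memory_differentiation	v1 MSI CRC IFNG+CD8 co-expression module; NFATC1,IL18R1 inferred	TOX	IL15RA	NFATC3	NFIL3	STAT1	STAT2	NFATC1	IL18R1
MSS_long_term_immunosurveillance	v1 MSS CRC IFNG+CD8 co-expression module	EOMES	PRDM1	KLRK1	KLRG1	IL2	TNF
MSS_inflamed_follicular_like	v1 MSS CRC IFNG+CD8 co-expression module	CXCR5	BCL6	CD28
MSS_inflamed_memory_like	v1 MSS CRC IFNG+CD8 co-expression module; IL18R1 inferred	TOX	PDCD1	CTLA4	NFATC2	NFATC3	SMAD2	SMAD3	SMAD4	STAT1	STAT2	IL15RA	IL18RAP	IL18R1
MSS_ifng_associated_dysfunctional	v1 MSS CRC IFNG+CD8 co-expression module	TBX21	YY1	NFIL3	CXCL9	CXCL10
MSS_tolerogenic_cmaf	v1 MSS CRC IFNG+CD8 co-expression module	MAF	ICOS	LAG3	TIGIT	ENTPD1	HAVCR2
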