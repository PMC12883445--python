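# SYNTHETIC example annotation of chromosome-X strata (hg38-style coordinates).
# These intervals are approximate placeholders for demonstration and testing
# only: real analyses should supply their own curated BED of evolutionary
# strata and ampliconic segments. Coordinates are 0-based half-open (BED).
chrX	10000	2781479	PAR1
chrX	2781479	58100000	XAR
chrX	58100000	62400000	centromere
chrX	62400000	88400000	XTR
chrX	88400000	155701382	XCR
chrX	155701382	156030895	PAR2
chrX	51000000	52100000	ampliconic-5
chrX	140000000	141000000	ampliconic-9
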