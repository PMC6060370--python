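chrom	start	end	lowest_p	genes	cutting	halter	racing	reining	western_pleasure	working_cow
1	40502663	40641889	0.000128973	PTEN,ATAD1	lhs	none	di	lhs	none	none
7	5501423	5596628	0.000068200	CERS4,CD320,RPS28	both	none	none	none	none	di
9	70643295	70822536	0.0000146	.	both	none	di	both	none	none
15	23550251	23566268	0.000127614	.	none	none	none	none	lhs	none
21	29967251	29989856	0.00006170	PRLR	lhs	lhs	lhs	lhs	none	none
21	31684806	31731726	0.00004790	NPR3	none	none	lhs	none	none	none
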