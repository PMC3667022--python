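# Significant differentially regulated unigenes per pairwise tissue comparison
tissue1	tissue2	total	up_in_t1	up_in_t2
Hepatopancreas	Gill	50757	33157	17600
Gill	Muscle	38511	33297	5214
Hepatopancreas	Muscle	53753	48362	5391
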