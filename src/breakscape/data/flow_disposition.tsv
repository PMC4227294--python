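profile	category	included	excluded
aneuploid	sufficient nuclei	21	0
aneuploid	insufficient nuclei	0	6
diploid	diploid tumors	2	0
diploid	diploid/tetraploid tumors	6	0
diploid	non-aberrant tumors or stroma only	0	5
diploid	insufficient nuclei	0	8
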