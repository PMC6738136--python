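# Toy VCF fixture

`toy.vcf` holds 12 hand-written records exercising the site filters
(depth >= 8 and at least one alternate allele at >= 10% of reads).
Enumeration by hand:

| POS  | DP  | AD       | outcome                                                        |
|------|-----|----------|----------------------------------------------------------------|
| 100  | 7   | 3,4      | excluded: depth 7 < 8                                          |
| 200  | 10  | 9,1      | kept: alt fraction 1/10 = 0.10 (boundary, ">=" keeps)          |
| 300  | 100 | 95,5     | excluded: alt fraction 0.05 < 0.10                             |
| 400  | 40  | 20,20    | kept: fraction 0.50                                            |
| 500  | 8   | 7,1      | kept: depth boundary 8, fraction 0.125 (insertion allele)      |
| 600  | 8   | 8,0      | excluded: alt fraction 0                                       |
| 700  | 30  | 20,10    | kept: fraction 1/3                                             |
| 800  | 50  | 44,4     | excluded: alt fraction 0.08 < 0.10                             |
| 900  | 40  | 30,6,4   | kept: alt G at 0.15 and alt C at 0.10 both pass (multiallelic) |
| 1000 | 12  | missing  | rejected: no AD field                                          |
| 1100 | 9   | 1,8      | kept: fraction 8/9                                             |
| 1200 | 7   | 0,7      | excluded: depth 7 < 8                                          |

Survivors: positions 200, 400, 500, 700, 900, 1100 (six records).

Allele-balance observations among the survivors (biallelic SNPs with both
alleles observed): positions 200 (y = 0.10), 400 (0.50), 700 (1/3) and
1100 (8/9). Position 500 is an insertion and 900 is multiallelic, so neither
yields an observation.
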