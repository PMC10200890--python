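# karyoploid

Computational companion to the cytogenomic analysis of a hypotetraploid
crucifer genome: the woodland herb *Catolobus pendulus*, the closest
relative of the model genus *Capsella*, whose 2n = 30 karyotype descends
from a whole-genome duplication of an Ancestral Crucifer Karyotype-like
diploid (ACK, n = 8) followed by chromosomal rediploidization.  The
package is for comparative cytogeneticists and population genomicists who
want to model block-level karyotype evolution explicitly and to run the
accompanying Hyb-Seq-style inferences (ploidy from allele frequencies,
ABBA-BABA introgression tests, cluster SNP partitioning) on their own or
simulated data.

## What it computes

**Karyotype model.** A genome is a gametic complement of chromosomes, each
an ordered, oriented list of segments of the 22 conserved genomic blocks
(A–X, with K-L and M-N atomic) with one centromere.  Rearrangement
operators: whole-genome duplication (WGD), end-to-end translocation (EET,
the dicentric fusion resolved by centromere elimination), reciprocal and
unequal translocations, and pericentric inversions.  Every operator except
WGD conserves block content exactly.  The packaged scenario replays the
origin of the *Catolobus* genome: WGD (2n = 32), an EET between the AK5
and AK7 homeologs (descending dysploidy to 2n = 30), then one reciprocal
translocation, two pericentric inversions and one unequal translocation.

**Parsimony search.** An iterative-deepening search over operator
applications recovers minimal rearrangement scenarios between two block
karyotypes, with breakpoints restricted to the sub-block cut points the
target exhibits and admissible lower bounds on mismatched chromosomes,
outstanding cuts and missing block adjacencies.

**Ploidy inference.** At a biallelic site the alternate-read frequency
concentrates near d/p for dosage d and ploidy p.  Fixed-mean Gaussian
mixtures (means 1/2; 1/3, 2/3; 1/4, 1/2, 3/4) are compared against a
free-mean mixture via Δ = logL(free) − logL(fixed), histogram regression
statistics (slope, SE, SSR, R²), and the median allele ratio
(max/min read count per site) placed against reference samples of known
ploidy.

**Introgression.** Patterson's D = (nABBA − nBABA)/(nABBA + nBABA) on
quartets (((P1,P2),P3),O), with a delete-one block jackknife over
contiguous site blocks giving Z = D/SE and a one-sided p; significance at
p < 0.01 and Z > 3.

**SNP partitioning.** After drawing equal samples per genetic cluster and
removing singletons, SNPs are split into shared, cluster-unique and mixed
sets, and cluster-specific genes are placed onto chromosomes through a
gene → genomic-block table.

**Synthetic data.** Seeded generators produce read counts at known ploidy
(negative-binomial depth, symmetric base error), quartet site patterns
with closed-form E[D] = γ/(2b + γ), cluster genotype tables with exact
partition structure, and random rearrangement scenarios — so every stage
is testable offline.

## Worked example

```python
import karyoploid as kp
from karyoploid.search import SearchConfig, search, event_kind_multiset

final, snapshots = kp.replay(kp.catolobus_scenario())
print(final.n, final.two_n)
# 15 30

print(kp.summarize(final, reference=snapshots[0]))
# {'n': 15, '2n': 30, 'block_copy_numbers': {...all 22 blocks: 2...},
#  'total_block_copies': 44, 'affected': 6}

for name in ("Cp11", "Cp12", "Cp13", "Cp14", "Cp15"):
    print(name, final.composition(final.get(name)))
# Cp11 Aa+Ca+B+Ab+Cb
# Cp12 Ab+B+C
# Cp13 Aa+O+P+Q+R
# Cp14 U+Fb+Ha+G+Fc+Hb
# Cp15 Fa+T+S+(K-L)+(M-N)

res = search(kp.apply_wgd(kp.build_ack()), final,
             SearchConfig(max_depth=5, max_scenarios=1))
print(res.distance, dict(event_kind_multiset(res.scenarios[0])))
# 5 {'EET': 1, 'UNEQ_TRANSLOC': 1, 'PERI_INV': 2, 'RECIP_TRANSLOC': 1}
```

The summary says: after the duplication 16 ancestral chromosomes carried
every block twice; the replayed history leaves 15 chromosomes (2n = 30)
still carrying all 44 block copies, six ancestral chromosomes structurally
changed, and the search independently certifies that no shorter history
(under the implied-breakpoint policy) explains the final complement than
the five published events.

The same operations are available from the shell:

```sh
karyoploid replay --scenario packaged --out cp.json --snapshots snaps/
karyoploid summarize --karyotype cp.json --reference snaps/step_00.json
karyoploid simulate counts --seed 7 --ploidy 4 --out sim/
karyoploid ploidy --input sim/site_counts.tsv
```

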