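# eqtlscan

Offline eQTL region scans: correlate SNP genotypes in a genomic region (or
an explicit SNP list) with the expression level of one gene, per transcript
probe, using per-SNP linear regression under a selectable genetic model.

Gene expression can be treated as a quantitative trait. For each SNP *j*
with genotype coding `x_ij` (additive: the count of minor alleles 0/1/2;
dominant / recessive: carrier / homozygote indicators; genotypic: additive
term plus a heterozygote-deviation term), `eqtlscan` fits

```
y_i = α + β x_ij + ε_i,          ε_i ~ N(0, σ²)
```

and tests β = 0 with the Wald statistic t = β̂ / se(β̂) on n−2 degrees of
freedom (for the 2-df genotypic model, a joint F(2, n−3) test of both
genotype terms). A variant whose genotype correlates with a transcript's
expression is an expression quantitative trait locus (eQTL); because no
cis-distance constraint is imposed, both cis scans (SNPs near the gene) and
trans scans (SNPs on another chromosome) work identically.

The toolkit is aimed at analysts who have PLINK-text genotypes (PED/MAP)
and a probe-level expression table for the same individuals — e.g.
HapMap-style reference panels with lymphoblastoid expression — and want
per-SNP effect sizes, p-values adjusted for multiple testing (Bonferroni,
Holm, Šidák, Benjamini–Hochberg, Benjamini–Yekutieli), and a UCSC Genome
Browser custom track of −log₁₀ p values, without any web service or
external downloads. A bundled simulator generates HapMap-shaped fixtures
(four populations, trio pedigrees in two of them, multi-probe genes) with
known ground truth.

## Worked example

Simulate a HapMap-shaped panel (270 individuals, 210 founders) with a
planted additive eQTL at `rs8` (β = 0.8, noise sd 0.6) shared by two
probes of `GENE1`, write it to disk, and scan the region:

```python
import eqtlscan as eq

cfg = eq.SimConfig(
    populations=eq.hapmap_populations(),        # CEU/CHB/JPT/YRI, 270 samples
    snps=eq.snp_grid(15),                       # chr4, 8,168,000 + 5 kb spacing
    causal=eq.CausalSpec("rs8", beta=0.8, noise_sd=0.6),
    n_probes_per_gene=2,
    seed=1,
)
ds = eq.simulate_genotypes(cfg)
profiles = eq.simulate_expression(ds, cfg)
paths = eq.write_fixture(ds, profiles, "demo")
```

```sh
eqtlscan --gene GENE1 --chrom 4 --from-bp 8168000 --to-bp 8790000 \
  --pop pooled --model additive \
  --ped demo/sim.ped --map demo/sim.map \
  --sample-info demo/sim.sample_info.tsv --expr demo/sim.expression.tsv \
  --out demo/out
```

prints

```
probe ILMN_000001: n=210, 15/15 SNPs tested, top SNP rs8 (p=2.833e-28)
probe ILMN_000002: n=210, 15/15 SNPs tested, top SNP rs8 (p=4.269e-31)
outputs in demo/out
```

n=210 because `--founders-only` (the default) drops the 60 trio children
before analysis; each probe is analyzed separately and the planted SNP is
recovered as the minimum-p SNP in both. `demo/out` then contains, per probe:

* `pvalues<PROBE>.linear.assoc.txt` — `CHR SNP BP A1 N BETA SE STAT P`;
  e.g. `4  rs1  8168000  A  210  -0.0383587  0.0832449  -0.460793  6.454283e-01`
  (A1 is the minor allele; BETA is expression change per copy of A1).
* `pvalues<PROBE>.linear.assoc.adjusted.txt` — `SNP RAW BONF HOLM SIDAK BH BY`.
* `<PROBE>.qassoc.means.txt` — per-genotype-class counts, means and SDs.
* `extracted_snps_with_expression_values<PROBE>.ped` — the merged PED with
  the expression value in the phenotype column.

plus `customtrack.txt`, one bedGraph block per probe × adjustment ready for
upload as a UCSC Genome Browser custom track:

```
track type=bedGraph name="ILMN_000001_raw" description="-log10 p (raw) for probe ILMN_000001"
chr4	8167999	8168000	0.190152
```

and `eqtlscan.log` with sample/SNP counts at every filtering step.

The same run is available from Python via `eq.run(eq.RunConfig(...))`.

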