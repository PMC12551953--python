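# indelfold

Insertion/deletion variants (indels) in 3'UTRs can change how strongly an
RNA-binding protein (RBP) binds a messenger RNA *without touching the
binding site itself*: by reshaping the RNA secondary-structure ensemble,
an indel tens of nucleotides away changes the energetic cost of exposing
the site. `indelfold` is a library and CLI for quantifying that effect and
for testing whether natural variation shows the fingerprint of purifying
selection against it. It is aimed at computational RNA biologists studying
regulatory variants around proteins such as HuR (ELAVL1), which binds
U-rich/AU-rich 3'UTR elements.

## The statistic

Protein binding is modelled as forcing the 7-nt binding site
single-stranded. With partition-function (ensemble) free energies `G`,

    dG  = G_constraint − G_none ≥ 0          cost of exposing the site
    ddG = dG_l − dG_s                         binding preference

where the l-allele and s-allele differ by exactly one indel. Positive ddG
means the protein prefers the shorter allele; direct protein contacts
cancel because the site sequence is identical on both alleles. Effects are
benchmarked against thermal energy k_BT ≈ 0.616 kcal/mol at 37 °C, and
aggregated as the standard deviation of ddG versus indel–site distance or
indel size, with percentile-bootstrap confidence intervals. Purifying
selection appears as a cohort (e.g. natural indels) whose SD curve sits
below a synthetic-indel cohort with separated CIs.

Folding free energies come from ViennaRNA (Turner 2004 nearest-neighbor
parameters, engine `nearest_neighbor`) or from a built-in exactly-testable
simplified model (engine `toy`, one energy per canonical pair) that is
verified against brute-force structure enumeration. The package also
identifies the most probable 7-nt binding site inside experimentally
resolved ~25-nt binding regions using affinity-weighted,
accessibility-corrected occupancy summed over both alleles, and generates
every input it needs synthetically (fragments, indels, dbSNP-style VCFs,
binding-region BEDs, RNAcompete-like affinity tables). See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```python
import indelfold as idf
from indelfold.pipeline import score_at_distance

# one 150-nt random fragment, deletion of 3 nt ending at position 100
frag = idf.random_fragment(idf.GeneratorConfig(seed=7))
pair = idf.synthetic_indel_fig1(frag, size=3)

# ddG at every 7-mer site in the downstream 50-nt window
obs = idf.sweep_sites(pair, engine="toy")
print(f"sites swept: {len(obs)}")
print(f"distance 0:  ddG = {obs[0].ddg:+.3f} kcal/mol")
print(f"distance 43: ddG = {obs[-1].ddg:+.3f} kcal/mol")

# dispersion of ddG over a 100-fragment cohort, near vs far from the indel
cohort = [idf.synthetic_indel_fig1(f, 3)
          for f in idf.random_fragments(idf.GeneratorConfig(seed=7, n_fragments=100))]
boot = idf.BootstrapConfig(resamples=1000, seed=1)
for d in (0, 30):
    pts = idf.build_curve([score_at_distance(p, d, "toy") for p in cohort],
                          "distance", boot)
    pt = pts[0]
    print(f"SD(ddG) at distance {d:>2}: {pt.sd:.3f} kcal/mol  "
          f"(95% CI {pt.ci_low:.3f}-{pt.ci_high:.3f}, n={pt.n})")
```

Output:

```
sites swept: 44
distance 0:  ddG = +0.179 kcal/mol
distance 43: ddG = -0.001 kcal/mol
SD(ddG) at distance  0: 0.408 kcal/mol  (95% CI 0.347-0.467, n=100)
SD(ddG) at distance 30: 0.028 kcal/mol  (95% CI 0.020-0.035, n=100)
```

The single-pair ddG values show one indel helping binding near the junction
(+0.179: the protein prefers the shorter allele there) and doing nothing 43
nt away. At the cohort level the dispersion of ddG is ~15× larger for sites
adjacent to the indel than for sites 30 nt away, with clearly separated
confidence intervals — the distance decay that makes nearby indels the
physiologically relevant ones.

## Command line

```bash
indelfold run fig2_random --out results/fig2 --seed 1 --engine toy --plots
indelfold run candidates  --out results/cand --seed 1
indelfold fixtures --out fixtures/ --seed 1 --n-transcripts 50
indelfold fold GGGAAACCCAUUGCACUCCGGUAA --site-start 4 --engine nearest_neighbor
```

Scenarios: `fig2_random`, `fig2_natural`, `fig3_sizes`, `fig5_categories`,
`fig6_hur`, `fig7_controls`, `s3_upstream`, `candidates`. Each writes
seeded, byte-reproducible TSV curves (and optionally PNG panels) plus run
metadata.

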