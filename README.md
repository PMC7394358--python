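# irscan

Gene-anchored detection of inverted repeats around phase-variable Type I
restriction-modification specificity genes.

## The problem

Type I restriction-modification (R-M) systems are three-gene loci
(*hsdR*–*hsdM*–*hsdS*) whose DNA recognition sequence is set by the
specificity protein HsdS, itself built from two half-site target recognition
domains (TRDs). Some loci carry a second, silent specificity gene (*hsdS′*)
encoding alternative TRDs between inverted repeats (IRs) shared with the
expressed copy. Recombination between the repeats swaps TRDs, switches the
methyltransferase's recognition sequence, and thereby flips a genome-wide
methylation pattern — a phase-variable regulon ("phasevarion"). These
"inverting" Type I loci matter for vaccine development and for understanding
bacterial gene regulation, so surveying annotated genomes for them is a
recurring task.

`irscan` is a toolkit for that survey, aimed at microbial genomicists:

* find all **maximal, 100%-identity inverted repeats ≥ 20 bp** between an
  annotated gene and its **30-kb flanks** (both bounds configurable),
* classify each locus as **inverting** (repeat partner lies in a second
  *hsdS*), **incidental IR**, or **no IR**, including a start-codon check on
  the silent copy,
* segment an *hsdS* gene into its **5′- and 3′-TRDs** from the repeat
  positions and enumerate the reachable **allele space** and population-level
  **methyltransferase-activity states**,
* generate **synthetic genomes** with planted loci, decoys, and an exact
  ground-truth table, so the whole pipeline is testable offline.

## The method

For a gene `g` and flank window `w`, the detector reports every maximal pair
(i, j, L) with

```
g[i .. i+L-1] = revcomp(w[j .. j+L-1]),   L >= min_ir_len (default 20 bp)
```

found by exact k-mer seeding (k = `min_ir_len`, tiles staggered by 1 bp) and
bidirectional extension to maximality, then filtered so that no reported hit
is contained in a longer one on both sides. Matching runs on the gene's
plus-strand slice — inversion is a genome-frame relation, symmetric in the
gene's reading direction — and coordinates are reported in coding
orientation. Only unambiguous A/C/G/T positions may participate in a match.
An independent O(n·m) dynamic-programming oracle
(`brute_force_inverted_repeats`) certifies the detector in the test suite.

Locus combinatorics: a gene with `n5` distinct 5′-TRDs and `n3` distinct
3′-TRDs yields `n5 × n3` alleles (labeled A, B, C, …); combined with `m`
independently ON/OFF-switching *mod* genes a population can express
`2^m × n5 × n3` distinct methyltransferase-activity states. Survey
percentages are truncated (not rounded) to one decimal.

## Worked example

Everything below is generated — no downloads. Simulate a genome carrying an
inverting locus plus four decoy repeats, scan it, classify it, and enumerate
its alleles:

```
$ irscan simulate --seed 7 --out-dir fixture --decoys all
$ irscan scan fixture/genome.fasta fixture/annotations.gff3 --out-dir results
4 hits across 5 genes -> results/hits.tsv

$ cat results/hits.tsv
gene_id       side        gene_start  gene_end  partner_contig  partner_start  partner_end  length  distance
hsdS          downstream  13          97        sim_contig      4950           5034         85      676
hsdS          downstream  368         400       sim_contig      4647           4679         33      373
hsdS_prime_1  downstream  13          97        sim_contig      3633           3717         85      676
hsdS_prime_1  downstream  368         400       sim_contig      3988           4020         33      373
```

The expressed *hsdS* carries two repeats (85 bp before its 5′-TRD, 33 bp
between the TRDs) whose partners sit inside the silent copy on the opposite
strand — the two rows per gene mirror each other. The 19-bp, mismatched,
beyond-window, and same-orientation decoys are all absent.

```
$ irscan classify results/hits.tsv fixture/annotations.gff3 fixture/genome.fasta --out-dir results
total hsdS genes          2
genes with >=1 IR         2
collated loci with >=1 IR 2
inverting                 2
percent inverting         100.0%

$ irscan alleles fixture/genome.fasta fixture/annotations.gff3 --gene hsdS --num-mod 2
gene             hsdS
partner          hsdS_prime_1
leader_ir        13-97
mid_ir           368-400
trd5             98-367
trd3             401-653
n_trd5_variants  2
n_trd3_variants  2
n_alleles        4
allele  A  5'-TRD-1  3'-TRD-1
allele  B  5'-TRD-1  3'-TRD-2
allele  C  5'-TRD-2  3'-TRD-1
allele  D  5'-TRD-2  3'-TRD-2
population_states  16
```

Two 5′-TRD variants × two 3′-TRD variants give a four-way switch (alleles
A–D); with two independently switching *mod* genes on top, a population can
present 16 distinct methyltransferase-activity combinations. Disjoint
phase-variation mechanisms combine additively:

```
$ irscan summarize --combine 2.0,7.9,3.9
13.8%
```

## Library use

```python
from irscan import SearchConfig, SimulationParams, simulate_genome, scan_gene

genome, annotations, truth = simulate_genome(SimulationParams(seed=1))
gene = next(a for a in annotations if a.gene_id == "hsdS")
hits = scan_gene(genome, gene, SearchConfig(min_ir_len=20, window=30000))
```

See `docs/methods.md` for the model, parameter defaults, numerical
conventions, and known limitations.
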