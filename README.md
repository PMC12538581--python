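# phagesite

Promoter-guided selection of payload insertion sites in bacteriophage genomes,
and design of the homologous-recombination donor constructs that put the
payload there.

## The problem

Engineering a phage to carry a genetic payload (a reporter such as
nanoluciferase, or an antimicrobial effector) requires choosing *where* in the
genome to integrate it. The conventional choice — just behind a
late-expressed structural gene like the major capsid gene — restricts payload
expression to the end of the infection cycle and sometimes fails to yield
viable progeny. `phagesite` instead searches the whole genome for intergenic
loci with favorable predicted expression, using machine-learning promoter
predictions (or a built-in σ70 consensus scanner) as a proxy for promoter
strength, and diversifies the selected sites across early-, middle- and
late-expressed gene clusters when temporal expression data are available.

## The method

1. **Search space.** Gene bodies are taken from an annotated GenBank record.
   Genes annotated in multiple parts (e.g. interrupted by intron-encoded
   homing endonucleases) are merged into one contiguous locus so no spurious
   insertion site opens between their parts. The promoter search space is the
   set of intergenic regions, each extended 50 bp into the flanking genes to
   catch promoters overlapping coding sequence.
2. **Scoring.** Each predicted promoter carries a probability-like score
   *s* ∈ [0, 1] (predictions below 0.5 are discarded). Scores are
   exponentially weighted, *w*(*s*) = e^*s*, to favor high-scoring
   predictions. The predictions of one strand inside one extended intergenic
   region form an **Intergenic Promoter Region (IPR)** with cumulative score

   &nbsp;&nbsp;&nbsp;&nbsp;IPR score = Σᵢ exp(*s*ᵢ).

   A single predicted promoter of score 0.921 therefore gives an IPR score of
   exp(0.921) = 2.51.
3. **Site selection.** IPRs are ranked by score. For each IPR the first
   downstream gene in the IPR's reading direction and orientation is found;
   the insertion site is the point immediately past that gene's stop. With a
   gene → early/middle/late table, the top-ranked site per temporal class is
   kept.
4. **Donor design.** Each site gets a donor fragment: 200–400 bp homology
   arms copied verbatim from the reference, flanking an RBS
   (`GAGGAGGTAAATATAT`) + payload cassette oriented to the selected gene's
   strand. If the gap to the next gene is under 20 bp, the last (20 − d)
   bases of the selected gene are duplicated after the payload so the
   downstream gene keeps an intact ribosome-binding-site context. The edit is
   also applied in silico and verified to conserve every annotated CDS.

## Worked example

Generate a synthetic 30 kb genome with three planted promoter clusters of
decreasing density and strength (5 motifs at mean score 0.95, 4 at 0.80,
3 at 0.60), then run the full pipeline:

```bash
phagesite simulate --seed 17 -o fx \
    --plant 1:+:5:0.95:0.03 --plant 5:+:4:0.80:0.05 --plant 9:+:3:0.60:0.05
phagesite run -g fx/genome.gb -p fx/predictions.tsv \
    --payload payload.fa --classes fx/classes.tsv -o out
```

`out/ipr_ranking.tsv` then contains:

```
rank  ipr_id           region_id  strand  span_start  span_end  n_members  ipr_score  selected_gene  temporal_class
1     ipr_ig_0001_fwd  ig_0001    +       1678        1978      5          12.7292    g001           early
2     ipr_ig_0005_fwd  ig_0005    +       7674        7920      4          8.7989     g005           middle
3     ipr_ig_0009_fwd  ig_0009    +       13343       13535     3          5.3459     g009           late
```

The densest planted cluster (5 members near score 0.95; Σ exp(sᵢ) ≈ 12.7)
ranks first, and each temporal class contributes one insertion site
(`out/insertion_sites.tsv`), placed just past the stop of the first gene
downstream of its IPR. `out/donors.fasta` holds the three donor fragments
(400 bp + cassette + 400 bp here), and `out/recombinant_site_*.gb` the
verified in-silico recombinants. Two plots (`score_histogram.png`,
`weighting_curve.png`) show the prediction-score distribution and the
exponential weighting.

The same stages are available individually (`phagesite regions`, `score`,
`select`, `design`) and as library functions (`phagesite.build_iprs`,
`phagesite.design_donor`, ...).

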