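# finishkit

A toolbox for *finishing* draft bacterial genomes with limited resources:
turning a fragmented shotgun assembly into a complete (or nearly complete)
genome sequence using information that is usually already at hand — the
adjacency evidence hidden in the assembly itself, optical restriction maps,
read depth, and the base composition of contig ends — before any wet-lab
experiment is ordered.

It is aimed at bioinformaticians in small labs and genomics cores who have a
draft assembly (contigs in FASTA), optionally one or two whole-genome optical
restriction maps, and want to know: in what order do the contigs lie, which
gaps can be closed purely in silico, which contig fills each remaining gap,
and how many PCR experiments is the rest going to take?

## What it computes

**Contig adjacency graph and in-silico closure.** Contigs are nodes; an edge
joins two contig *ends* (B = beginning, E = end of the forward strand)
whenever reads span them. Read depth estimates each contig's copy number
(*multiplicity*) *m(c)* = max(1, round(depth(c) / baseline)), with the
baseline the length-weighted median depth of long contigs. The genome is a
walk that uses every edge exactly once and every contig exactly *m(c)* times
— an Eulerian-style traversal. `finishkit` checks the degree conditions
(every end's degree must equal its contig's multiplicity for a circular
genome) and enumerates walks by backtracking; if exactly one walk exists up
to rotation and reverse complement, the genome is reconstructed by gluing
the contigs along it. A 2-copy repeat interleaved as U₁ R U₂ R resolves
uniquely; a 3-copy repeat does not (two interleavings), which is exactly
when a targeted PCR is still needed.

**Optical-map placement.** Each contig is digested in silico with the map's
enzyme and its internal restriction fragments are aligned to every window of
the ordered genome-wide map by dynamic programming. A matched block pairing
expected length *e* with observed length *o* costs
(*o* − *e*)² / (*s·e* + (*cv·e*)²), plus penalties for unmatched cuts
(missed cuts in the map, false cuts, and cheap skips next to the detection
floor, which the instrument cannot see reliably). A placement is *unique*
only when every rival location scores at least a margin worse than the best.
Contigs with fewer than two map-resolvable fragments are never placed.

**Multi-enzyme merging.** Placements from maps made with different enzymes
(AflII and NheI are built in) are registered on a common coordinate frame
through an *anchor* contig placed uniquely on every map, tested for
distance-to-anchor consistency, disambiguated across maps, and committed
nearest-to-anchor first. A second enzyme rescues contigs that have too few
sites for the first — the main practical payoff of paired maps.

**Graph-augmented finishing.** The map scaffold and the contig graph
validate each other: consecutive placements should be joined by an edge or
by a connecting path of repeat contigs whose implied length matches the map
gap. Unplaced contigs linking both flanks of exactly one gap are inserted;
a gap with exactly one length-consistent connecting path is closed in
silico, consuming repeat multiplicity so no contig is used more often than
its copy number. Remaining gaps get candidate fillers ranked by GC match of
1 kbp contig ends against the gap flanks.

**Experiment planning.** Ordering *n* unordered contigs by pairwise PCR
needs on the order of *n*² reactions; a genome-wide scaffold reduces that to
one reaction per gap (*n* − 1 linear, *n* circular).

## Worked example

Simulate a 300 kbp circular genome with a 2-copy 5 kbp repeat (an
rRNA-operon-like situation), then close it from contigs and links alone:

```
$ finishkit simulate --length 300000 --repeat rrn:5000:2 --seed 5 \
      --out-prefix demo --noise-links 3
wrote demo.* (3 contigs, 7 links)

$ finishkit graph build demo.contigs.fasta demo.links.tsv demo.coverage.tsv
node    u3u1    131957  32.6    1
node    rep_rrn 5000    61.9    2
node    u2      158043  31.5    1
edge    rep_rrn.B       u2.E    7       0
edge    rep_rrn.B       u3u1.E  5       0
edge    rep_rrn.E       u2.B    10      0
edge    rep_rrn.E       u3u1.B  6       0

$ finishkit graph traverse demo.contigs.fasta demo.links.tsv demo.coverage.tsv \
      --out-fasta closed.fasta
verdict unique  topology        circular
walk    rep_rrn+ u2+ rep_rrn+ u3u1+
wrote closed.fasta (300000 bp)
```

The assembler collapsed the repeat into one contig (`rep_rrn`, depth 61.9 ≈
2× the ~32× baseline, hence multiplicity 2); the four end-links admit
exactly one circular walk, so the 300 kbp genome is reconstructed gap-free
— no PCR required. Note the 3 spurious single-read links were filtered by
the default support threshold of 2.

Scaffolding the same contigs on a simulated noisy AflII optical map, and
estimating the PCR effort the paper-scale case (59 large contigs) would
need without a scaffold:

```
$ finishkit scaffold-map demo.contigs.fasta demo.AflII.map --agp demo.agp
2 contigs scaffolded, 62.2% of map covered -> demo.agp

$ finishkit plan --n 59
mode unordered: 3481 experiments (~3000; pairwise n(n-1)/2 = 1711)
```

`demo.agp` is standard AGP v2.0; the repeat contig is too short to carry
two map-resolvable restriction fragments and is left to the graph stage,
which is exactly what `finishkit close-gaps` / `finishkit report` then
resolve.

## Layout

```
src/finishkit/
  core_io.py            FASTA / restriction-map / links TSV / PAF / AGP I/O
  contig_graph.py       adjacency graph, multiplicities, unique traversal
  optical_placement.py  in-silico digestion and DP map placement
  map_merge.py          multi-enzyme placement merging
  finishing.py          validation, gap closure, GC matching, PCR planning
  simulate.py           synthetic genomes, links, coverage, noisy maps
  cli.py                the `finishkit` command
docs/methods.md         models, parameters, calibration, limitations
```
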