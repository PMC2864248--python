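# Methods

This note documents the models behind `finishkit`, the parameters that
matter, how the synthetic data used by the test suite is generated, and the
numerical choices made where the design was genuinely open.

## Contig adjacency graph

Nodes are contigs; an edge joins two contig ends and records the number of
spanning reads supporting the adjacency (`support`) and the implied
distance between the ends (`offset_bp`: negative = overlap, positive =
gap). Links below `min_support` (default 2) are discarded — a single
spanning read is too easily a chimera or mismapping. Duplicate end-pair
links are aggregated by summing support and taking the median offset, which
is robust to the occasional mis-measured spanning read.

Edge multiplicity is fixed at one: if a genome requires the same junction
to be crossed twice, the degree conditions fail and the verdict is
`inconsistent` or `multiple` rather than a guessed reconstruction. This is
a documented limitation; such cases need targeted experiments anyway.

### Multiplicity estimation

The single-copy depth baseline is the length-weighted median depth of
contigs at least `base_length` (default 10 kbp) long; in a bacterial draft
the long contigs are overwhelmingly single-copy, and the length weighting
makes the median insensitive to a few long repeats. Multiplicity is
`max(1, round(depth / baseline))`. If no contig reaches `base_length` the
median is taken over all contigs, with a warning — correct only when most
of the assembly is single-copy.

### Unique traversal

A circular genome corresponds to a closed walk using every edge exactly
once and every contig exactly its multiplicity times; a linear genome to an
open walk with exactly two end-degree deficiencies. The implementation
first checks the degree conditions (each end's degree must equal its
contig's multiplicity; for linear genomes exactly two ends deficient by
one) and graph connectivity, then enumerates walks by backtracking from a
canonical start (the lexicographically smallest contig, forward). Two
walks are the same reconstruction when they are identical up to rotation
(circular) and global reverse complement — both describe the same
molecule. Enumeration stops at the second distinct walk (`multiple`) or
when the step budget (`max_steps`, default 10⁶) is exhausted
(`undetermined`): the worst case is exponential, and an undetermined
verdict is more honest than an unbounded search.

The test suite checks the traversal against an independent brute-force
walk enumerator on randomly generated walk-induced graphs (≤ 8 contigs,
total multiplicity ≤ 12), including randomly damaged ones.

### Reconstruction

Contigs are glued along the walk. A negative junction offset is merged
only after verifying ≥ 95 % identity across the overlap (tolerant of
homopolymer-type indel errors in 454-era data); the earlier contig's copy
is kept. Positive offsets are filled with Ns. Circular reconstructions
are rotated to start at the smallest contig id in forward orientation; a
negative offset at the wrap junction trims the trailing copy of the
overlap, which is equivalent as a circular molecule.

## Optical-map placement

### Score model

The contig's internal restriction fragments are aligned to map windows by
dynamic programming over monotone cut-to-cut matchings. A matched block
(≤ `delta` fragments merged on either side, default 4) costs

    (o − e)² / (s·e + (cv·e)²)

where `e`/`o` are the expected (sequence) and observed (map) block lengths.
The variance has a Poisson-like floor `s·e` (default s = 30 bp) plus a
relative-error term (`cv` = 0.05) matching the multiplicative sizing error
of optical mapping; a pure `s·e` form under-penalizes mismatches on large
fragments and lets spurious windows score deceptively well. Unmatched cuts
cost `c_miss` = 1.5 (contig cut invisible in the map) or `c_false` = 3.0
(map cut with no sequence counterpart), discounted to `c_floor` = 0.5 when
the skipped cut is flanked by a fragment within 1.2× of the detection
floor — whether such a fragment is resolved is an instrument coin-flip,
not evidence against the placement. A placement additionally pays a global
span-consistency term with variance summed over the matched fragments;
sizing errors accumulate over the window, so a spurious placement that
compresses or stretches the whole contig is penalized even when each block
individually fits.

Terminal partial fragments constrain but do not score: each must fit into
the map region beyond the boundary cut within a slack of 10 % of its
length plus one detection floor; the region may span several map fragments
(a false cut, or the arbitrary origin cut of a circular map, can subdivide
a long cut-free terminal region), at `c_false` per swallowed cut. Up to
`delta` − 1 leading/trailing contig fragments may be skipped at `c_miss`
each, so a missed boundary cut does not kill the whole contig.

### Conditioning

Optical maps cannot resolve fragments below a detection floor (`min_frag`,
default 2000 bp); sub-floor fragments merge into their smaller neighbour.
The same conditioning is applied to the contig digest before alignment so
both fragment patterns have the same statistics. Placement requires at
least two conditioned (map-resolvable) internal fragments; contigs below
that are reported `unplaced` with reason "too few sites" and are left to
the graph stage.

### Acceptance and uniqueness

The best placement is accepted when its mean score per conditioned
fragment is at most `t_max` (default 2.0). Candidate placements
overlapping by more than `overlap_collapse` (default 0.5) of the shorter
interval *in the same orientation* are the same location (a ±1-fragment
shift) and collapse to the best; an opposite-strand overlap is a genuine
rival. The placement is `unique` only when every remaining rival scores at
least `margin` (default 0.8) worse; otherwise `ambiguous`. The margin is a
log-likelihood-style separation: it was calibrated on simulated genomes as
the knee of the recall/false-placement trade-off (see Calibration).

## Multi-enzyme merging

Maps from different enzymes are registered via an anchor contig placed
uniquely on every map (the longest such contig; ties broken by id). Each
map is mirrored if the anchor was placed in reverse, rebased so the anchor
starts at 0, and rescaled by the ratio of total map lengths — optical
sizing bias is approximately multiplicative, so a single global scale
aligns the coordinate frames. Cross-map agreement uses a tolerance of
`max(10 kbp, 5 % of the distance to the anchor)`: absolute for nearby
contigs, relative far away where scale error dominates. Contigs unique on
one map only are kept as-is (the second enzyme's whole point); ambiguous
contigs are resolved by a unique placement on another map or by a uniquely
agreeing combination of candidates. Placements are committed nearest-to-
anchor first, dropping any whose interval overlaps an earlier one by more
than `max(5 kbp, 20 % of the shorter)`.

## Graph-augmented finishing

Scaffold junction validation asks, for each consecutive pair of placed
contigs, whether the facing ends share an edge (`direct`), are joined by a
connecting path of intermediate contigs whose implied length fits the map
gap (`path`), or neither (`none`). The gap budget is
`gap + max(5 kbp, 30 % of gap)` — map gaps inherit sizing noise roughly
proportional to their size, with a floor for small gaps.

Unplaced contigs are inserted into a gap when they link both flanks with
consistent orientation and fitting length; a contig consistent with
several gaps is inserted into all of them only if its multiplicity covers
them (the rRNA-operon case), otherwise left out. Gap closure proceeds in
ascending gap size (small gaps are most reliable, and early closures
constrain the multiplicity budget for later ones); a gap closes only when
exactly one length-consistent path exists and every member contig has
multiplicity left, which is then consumed. All ambiguity resolves to
"leave open": a missing join costs a PCR, a mis-join costs a mis-assembled
genome.

GC matching scores a candidate filler as the sum of absolute GC
differences between the gap's two flank ends and the candidate's
corresponding ends, over 1 kbp windows (both candidate orientations tried,
best kept; GC computed over unambiguous bases). Candidates are unplaced
contigs ≥ 10 kbp with multiplicity remaining. The method works because
bacterial base composition is regionally coherent — a filler native to a
GC-distinct neighbourhood matches both flanks of its own gap.

Experiment planning reports the all-pairs n² figure for unordered contigs
(with n(n−1)/2 alongside) and one experiment per gap once scaffolded, plus
the facing end-pairs a primer design would target.

## Synthetic data

The simulator emulates what a high-coverage short-read bacterial project
hands to a finishing pipeline, and is the basis of every quantitative test:

* **Genome**: i.i.d. bases at a target GC (default 0.5), optional
  GC-distinct islands (overwritten into the background *before* repeats so
  repeat copies stay exact), and exact repeat families pasted at
  non-overlapping positions, each copy in random orientation unless pinned.
  Exact copies reflect the assumption that conservative assemblers collapse
  near-identical repeats into one contig.
* **Contigs**: one per unique inter-repeat segment plus one per repeat
  family; on a circular genome the two segments flanking the origin fuse
  into one wrap-around contig. Alternatively, `tile_contigs` cuts a genome
  into consecutive random-strand windows for placement studies.
* **Links**: every true junction, with Poisson support (mean 5–6) and
  optional spurious support-1 links joining random non-adjacent ends,
  which the default `min_support = 2` filter removes.
* **Coverage**: `base_depth × multiplicity` with 10 % multiplicative noise.
* **Optical maps**: true cuts dropped with `p_miss` = 0.05, false cuts as
  a Poisson process at 1 per 100 kbp, fragment lengths resampled with
  relative s.d. `sigma_rel` = 0.03, and sub-floor (< 2000 bp) fragments
  merged into their smaller neighbour. The genome coordinate of map
  position 0 is tracked through the merging so simulation truth checks do
  not inherit the circular map's arbitrary origin.

Everything is deterministic under its seed, and generators emit a JSON
sidecar recording the spec and true layout.

What the simulator does *not* model: sequence divergence between repeat
copies (a knob exists but is untested territory), chimeric reads, coverage
biases correlated with GC, structural mis-assemblies inside contigs, and
optical-map assembly errors beyond the per-fragment noise above. Passing
tests therefore demonstrate correctness of the algorithms under the stated
error model, not robustness to pathological real-world artefacts.

## Calibration and problem sizes

The placement score constants (`s`, `cv`, penalties, `delta`, `margin`,
collapse threshold) were calibrated on simulated 500 kbp circular genomes
tiled into 7 contigs of ≥ 30 kbp — matching the real-data regime the
toolbox targets (a ~4.6 Mbp genome in ~59 large contigs averages ~79 kbp
per contig, against map fragments averaging ~11 kbp). On seed blocks held
out from calibration, 92–96 % of contigs with ≥ 4 map-resolvable fragments
place uniquely within 5 kbp of truth in the correct orientation under the
default noise model, with ~1 % placed uniquely but wrongly; with all noise
terms off, placement is exact and unique for every contig with ≥ 2
internal fragments. Test and demonstration genomes run at 0.2–1 Mbp with
maps of 70–200 fragments; the algorithms scale to full bacterial genomes
(the DP is linear in map size per anchor and quadratic in the merge bound).

## Known limitations

* Graphs needing the same edge twice, or repeats in inverted orientation
  at 2 copies, yield `multiple`/`inconsistent` rather than a
  reconstruction — by design, but it means some resolvable-by-eye cases
  are left to experiments.
* Placement of contigs with 2–3 map-resolvable fragments is frequently
  `ambiguous`; the information simply is not there at realistic map
  densities, and the conservative verdict is deliberate.
* The merge step trusts the first (reference) map's coordinates when maps
  agree; systematic non-multiplicative sizing bias between maps is not
  modelled.
* AGP output represents circular scaffolds linearly; the wrap junction is
  not encoded.
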