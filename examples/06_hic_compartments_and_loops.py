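"""Hi-C compartment strength, range fractions, and lost-loop target genes.

Compartment scores come from the leading eigenvector of the O/E correlation
matrix, sign-phased so positive = A; saddle strength compares extreme
same-compartment contact enrichment against the cross-compartment corner.
Long-range loops present only in the parental condition are traced through
anchor enhancers to their nearest genes.
"""

import numpy as np

from epiredist.compartments import (
    cis_range_fractions,
    compartment_score,
    oe_transform,
    saddle_strength,
)
from epiredist.genome import BinnedTrack
from epiredist.loops import find_lost_loops, loop_anchor_enhancer_genes
from epiredist.simulate import (
    make_genome_annotation,
    simulate_contact_maps,
    simulate_expression_response,
)

layout, genes, enhancers, truth = make_genome_annotation(seed=1)
matrices, loop_sets = simulate_contact_maps(truth)
deltas = simulate_expression_response(truth)

probe = BinnedTrack(layout, 100_000, np.zeros(layout.total_bins(100_000)), "count")
dom = probe.region_weights(truth.domains)
offsets = layout.bin_offsets(100_000)
n_bins = layout.n_bins(100_000)

for cond in ("parental", "treated"):
    aa, bb, fl = [], [], []
    for chrom, m in matrices[cond].items():
        phasing = -dom[offsets[chrom]: offsets[chrom] + n_bins[chrom]]
        score = compartment_score(m, phasing)
        res = saddle_strength(oe_transform(m), score)
        aa.append(res.strength_aa)
        bb.append(res.strength_bb)
        fl.append(cis_range_fractions(m)[0])
    print(f"{cond:>9}: strength A-A = {np.mean(aa):.2f}, "
          f"B-B = {np.mean(bb):.2f}, long-range cis fraction = {np.mean(fl):.3f}")

lost = find_lost_loops(loop_sets["parental"], loop_sets["treated"])
assoc, summary = loop_anchor_enhancer_genes(lost, enhancers, genes, deltas)
print(f"loops: {len(loop_sets['parental'])} parental, "
      f"{len(loop_sets['treated'])} treated, {len(lost)} lost (> 500 kb)")
print(f"lost-loop target genes: {summary['n_down']} down / {summary['n_up']} up "
      f"(rank-sum p = {summary.get('ranksum_p', float('nan')):.2e})")
print("-> compartment checkerboarding weakens in the treated condition and the")
print("   genes wired to the lost long-range loops are preferentially repressed.")
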