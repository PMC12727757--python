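"""Metagene invasion profiles stratified by expression.

Genes in the interquartile length band without close neighbours are split
into silent / lowly / highly expressed groups; for each, signal over a scaled
gene body plus fixed flanks is averaged.  In the treated condition the mark
invades gene bodies in proportion to expression.
"""

import warnings

import numpy as np

from epiredist.metagene import MetageneParams, compute_metagene_matrix, select_gene_groups
from epiredist.simulate import make_genome_annotation, simulate_mark_tracks
from epiredist.tracknorm import depth_normalize, ms_calibrate

_, genes, _, truth = make_genome_annotation(seed=1)
_, treated, _, cal = simulate_mark_tracks(truth)
ms = ms_calibrate(depth_normalize(treated, float(treated.values.sum())),
                  cal.pct("H3K9me3", "treated"))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # desk-scale pools are smaller than n
    groups = select_gene_groups(genes, n=20, seed=1)

params = MetageneParams()
print(f"matrix geometry: {params.n_columns} columns "
      f"({params.upstream} bp flank + {params.body} bp scaled body + "
      f"{params.downstream} bp flank at {params.bin} bp bins)")
for name in ("silent", "low", "high"):
    ids = getattr(groups, name)
    if not ids:
        print(f"{name:>6}: empty group")
        continue
    matrix, agg = compute_metagene_matrix(ms, genes, ids, params)
    body = float(np.mean(agg[4:44]))
    print(f"{name:>6}: n={len(matrix):3d}  mean body signal = {body:.2f}%")
print("-> gene-body invasion of the treated mark increases with expression,")
print("   the signature of transcription-coupled ectopic deposition.")
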