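"""Validate short-read TIP calls of one accession with long reads.

Long reads containing a TE junction are identified (a consensus hit must
cover at most 80 % of the read, otherwise the read lies wholly inside an
element), 300-bp flanks are mapped back to the reference, and the resulting
insertion loci are compared with the short-read calls window by window.
"""

from tipscan import detect, simulate
from tipscan.longread import compare_callsets, find_te_reads, map_insertions

study = simulate.simulate_study(seed=7, length=400_000, n_accessions=4,
                                n_loci=12, repeat_fraction=0.3)
res = detect.detect_tips(study.reads, study.library, study.reference.genome)

acc = study.panel.accessions[0]
reads = simulate.generate_long_reads(study.panel.genomes[acc], coverage=11,
                                     error_rate=0.0, seed=41)
jreads = find_te_reads([(f"lr{i}", r) for i, r in enumerate(reads)],
                       study.library)
insertions = map_insertions(jreads, study.reference.genome)
tips = [(c.family_id, c.window_id) for c in res.calls
        if c.accession_id == acc]
s = compare_callsets(tips, insertions, res.windows)

print(f"{len(reads)} long reads, {len(jreads)} junction reads, "
      f"{len(insertions)} mapped insertions")
print(f"short-read TIPs: {s.n_tips}, long-read loci: {s.n_longread_loci}")
print(f"TP={s.tp} FP={s.fp} FN={s.fn}")
print(f"specificity {s.specificity}   (fraction of TIP calls confirmed)")
print(f"sensitivity {s.sensitivity}   (fraction of long-read loci also "
      "called from short reads)")
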