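"""Classify and date insertions across three simulated assemblies.

Full elements are discovered by RT-domain search and LTR recovery in each
assembly, assigned to one of seven presence categories by flank-anchored
orthology across the trio, validated against a panel matrix, and dated with
the LTR clock.  Shared (pre-split) insertions come out older than the
group-specific (post-split) ones.
"""

from tipscan import simulate
from tipscan.align import SeedAligner
from tipscan.paleo import (DatedInsertion, category_age_distributions,
                           classify_insertion, date_insertion, find_ortholog,
                           find_paralogs, ltr_identity, recover_full_element,
                           validate_category)

trio = simulate.simulate_trio(seed=3, per_category=3)
matrix, groups, windows = simulate.trio_panel_matrix(trio, seed=4)
gids = list(trio.genomes)
jap, ind, aus = gids
aligners = {g: SeedAligner(dict(trio.genomes[g])) for g in gids}

dated = []
for gid in gids:
    for fam in trio.library:
        for locus in find_paralogs(fam, trio.genomes[gid]):
            el = recover_full_element(locus, fam, trio.genomes[gid], gid)
            if el is None:
                continue
            flags = {gid: "present"}
            for other in gids:
                if other != gid:
                    flags[other] = find_ortholog(el, trio.genomes[gid],
                                                 trio.genomes[other], fam,
                                                 target_aligner=aligners[other])
            if "unresolved" in flags.values():
                continue
            cat = classify_insertion(flags[jap], flags[ind], flags[aus])
            ident = ltr_identity(el, trio.genomes[gid])
            ok, _ = validate_category(el, cat, matrix, groups, windows[gid])
            dated.append(DatedInsertion(el, ident, date_insertion(ident),
                                        cat, ok))

table = category_age_distributions(dated)
print(table.to_string(index=False,
                      float_format=lambda x: f"{x:,.4g}"))
print("\n(identity medians translate to ages via the 1.3e-8 /site/year clock;"
      "\n elements found in several assemblies are dated in each)")
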