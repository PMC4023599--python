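"""Genome organization of the packaged 55-member grapevine family.

Loads the packaged family table, computes the chromosome distribution,
checks for tandem arrays among collinear duplicates, and summarizes the
duplicate relation into connected components (pairs/triplets).
"""

from bzipkit.organization import (
    chromosome_distribution,
    detect_tandem,
    summarize_collinearity,
)
from bzipkit.records import CollinearityBlock, CollinearityFile
from bzipkit.simulate import table1_fixture

table = table1_fixture()
d = chromosome_distribution(table)
print(f"{len(table)} genes; {d.mapped_total} mapped, {d.unmapped} on unplaced scaffolds")
print(f"chr18 holds {d.counts['18']} genes ({d.percentages['18']}% of mapped)")
print(f"chromosomes without family genes: {', '.join(d.empty_chromosomes)}")

pairs = {
    ("VvbZIP07", "VvbZIP13"),
    ("VvbZIP13", "VvbZIP47"),
    ("VvbZIP14", "VvbZIP22"),
    ("VvbZIP22", "VvbZIP37"),
}
print(f"tandem arrays among collinear duplicates: {len(detect_tandem(table, pairs))}")

coll = CollinearityFile([CollinearityBlock(str(i), [p]) for i, p in enumerate(sorted(pairs))])
summary = summarize_collinearity(coll, table)
for comp in summary.triplets:
    print("triplicate genes:", "/".join(sorted(comp)))

# The uneven distribution (11 genes on chr18, none on 9/10/11/16/17), the
# absence of tandem arrays, and the two triplicates are the hallmarks of
# expansion through segmental duplication rather than local duplication.
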