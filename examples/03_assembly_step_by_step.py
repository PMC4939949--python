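"""The assembly machinery, one stage at a time.

Fragments a single sampled homolog into overlapping error-free reads and
walks through seeding, overlap-link construction, guided assembly and
contig recalibration, printing what each stage produces.

Run:  python examples/03_assembly_step_by_step.py
"""

import numpy as np

from prosaa import (AssemblyParams, PeptideRead, ReadDatabase,
                    assemble_family, build_extension_links, build_kgram_index,
                    find_seeds, random_profile_hmm, recalibrate,
                    sample_from_hmm, to_scoring)

model = random_profile_hmm(80, seed=11, name="ASM")
scoring = to_scoring(model)
protein, _ = sample_from_hmm(model, np.random.default_rng(2))
print(f"homolog protein: {len(protein)} aa")

# fragment into 25-aa reads every 6 residues (19-aa overlaps)
reads = [protein[s:s + 25] for s in range(0, len(protein) - 24, 6)]
db = ReadDatabase([PeptideRead(f"r{i}", s, i) for i, s in enumerate(reads)])
print(f"{len(db)} overlapping reads")

params = AssemblyParams()
kindex = build_kgram_index(db, params.k)
links = build_extension_links(db, params.min_overlap)
print(f"k-gram index: {kindex.n_entries()} entries; "
      f"overlap graph: {links.n_links()} extension links")

seeds = find_seeds(scoring, kindex, params.theta)
print(f"{len(seeds)} seeds; best anchors read {seeds[0].read} at model "
      f"position {seeds[0].i0} ({seeds[0].seed_score:.1f} bits)")

contigs = assemble_family(scoring, db, kindex, links, params, seeds=seeds)
print(f"assembly emitted {len(contigs)} contig snapshots")

final = recalibrate(contigs, params.min_overlap)
print(f"after recalibration: {len(final)} contig(s)")
best = max(final, key=len)
print(f"longest contig: {len(best)} aa from {len(best.reads)} reads "
      f"({100 * len(best) / len(protein):.0f}% of the homolog)")
assert best.seq in protein
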