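"""Scan a designed sequence for 9-mers shared with a reference proteome.

Generates a decoy proteome, deliberately plants two windows of the query
into it, and shows that the exact 9-mer index reports precisely those.
"""

import numpy as np

import epigraft as eg

rng = np.random.default_rng(11)
query = "".join(rng.choice(list(eg.humanness.AMINO_ACIDS), size=50))
proteome = eg.generate_proteome(25, (80, 120), seed=42)
proteome, truth = eg.plant_shared_windows(
    query, proteome, [(7, proteome[4].id, 30), (21, proteome[9].id, 55)]
)

index = eg.build_kmer_index(proteome, k=9)
report = eg.scan_sequence(query, index, query_id="designed-immunogen")

print(f"proteome: {index.n_proteins} proteins, {len(index.window_map)} distinct 9-mers")
print(f"query: {len(query)} residues, {report.n_windows} windows scanned")
print(f"matches: {report.n_matched_windows} "
      f"(planted: {len(truth)}) in {report.distinct_proteins_hit} proteins")
for m in report.matches:
    src = ", ".join(f"{pid}@{s}" for pid, s in m.sources)
    print(f"  query position {m.query_start}: {m.window} found in {src}")
print("\nEach match is a 9-residue self-peptide the immunogen would share "
      "with the reference proteome — the windows the design stage must remove.")
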