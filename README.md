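# epigraft

Epitope grafting and proteome-9-mer deimmunization for scaffold-based
immunogen design.

## The problem

Vaccinating against a self-protein — for example PCSK9, the secreted liver
protein that routes LDL receptors to degradation and thereby raises blood
LDL cholesterol — faces immune tolerance: the immune system will not
readily mount a response against peptides it recognizes as self. One way
around tolerance is a *mimic*: take a divergent homolog of the antigen
(e.g. a fish ortholog) as a scaffold, transplant onto it exactly the
surface patches that the receptor and therapeutic antibodies bind, and
then mutate away every peptide the construct still shares with the host
proteome. The result presents the functional epitopes of the self-protein
on an otherwise foreign molecule that contains **no 9-residue stretch in
common with any host protein** — the length scale relevant to T-cell
epitope presentation.

`epigraft` implements this design computation as a reusable pipeline:

1. **Footprint** — per-residue buried surface area (BSA) of the donor
   antigen against each binding partner, from complex structures
   (PDB/mmCIF):
   `BSA(r) = Σ_atoms [SASA_isolated(a) − SASA_complex(a)]`,
   with SASA from a deterministic Shrake–Rupley quadrature
   (golden-spiral point set, default n = 960, probe 1.4 Å).
2. **Stretch selection** — donor positions with BSA ≥ threshold
   (default 1.0 Å²) against ≥ `min_partners` partners (default 2) are
   merged into contiguous epitope stretches, bridging up to `gap_merge`
   (default 2) intervening residues.
3. **Graft** — a global alignment (BLOSUM62, gap open −11 / extend −1)
   maps donor positions onto the scaffold; stretch residues are
   transplanted, recording substitutions, insertions and deletions.
4. **Dehumanize** — an exact index of every length-9 window of the
   reference proteome is built; greedy constrained point mutation
   destroys every shared window: each step picks the (position,
   replacement) destroying the most matched windows without creating any
   new indexed window, with replacements restricted to residues observed
   among species variants of the antigen and the transplanted epitope
   positions locked.
5. **Liability variants** — named substitutions (e.g. cleavage-site
   removals such as K21Q, R218E) applied with a from-residue guard.

A seeded synthetic-data module generates decoy proteomes with planted
shared 9-mers, toy two-chain complexes with analytically known contact
geometry, and species-variant alignments, so the whole pipeline is
testable end to end with no downloads.

## Worked example

`python examples/03_graft_and_dehumanize.py` (the other examples cover
the footprint stage, the proteome scan, and the file-driven pipeline):

```
donor:    WPQVNSTFCHGVWALTDSDLTHHGRGYKLMNNMYTSRPHY
scaffold: TPEDNSTFCMCVEAPSYSDLTVHGRGYQIINNMYTSTPAI
grafted:  TPEDNSTFCMCVWAPSYSDLTVHGRGYQIINNMYTSTPAI
transplanted positions: [5, 6, 7, 8, 12, 13, 14] (1 substitutions)

shared 9-mers before dehumanization: 2
status: clean
  mutation I30Q destroyed windows at [22, 30]
residual shared 9-mers: 0
epitope intact: True
```

The two epitope stretches (donor 5–8 and 12–14, buried by both toy
partners) are carried over onto the scaffold — here only E13W actually
differs. The grafted sequence shares two 9-mers with the decoy proteome
(windows starting at 22 and 30); they overlap at position 30, so a single
mutation I30Q — to a residue observed at that column among species
variants — destroys both. The final construct keeps every transplanted
epitope residue and shares no 9-mer with the proteome.

The same run from a shell:

```sh
epigraft synth --seed 7 --out fx      # write the synthetic study + config
epigraft run --config fx/config.yaml  # five stages, reports in fx/run/
```

Every stage is also available as its own subcommand (`footprint`,
`stretches`, `graft`, `scan`, `dehumanize`, `apply-variants`) reading and
writing FASTA/PDB/TSV/JSON, and as plain library calls.

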