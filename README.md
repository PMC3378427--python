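# alloasm

De novo transcriptome assembly of an **allopolyploid** is hard for a
reason that is easy to state: every gene is present as two homeologous
copies — one per parental subgenome — that are 85–95% identical, while
sequencing reads are far shorter than the distance between many of the
copy-discriminating sites. A de Bruijn graph assembler therefore has to
choose, jointly, a k-mer size *k* and a k-mer coverage cutoff *c*, and
that choice decides which transcripts come out complete, which fragment,
and which collapse into chimeras that mix the two copies.

`alloasm` is a desk-scale laboratory for studying exactly that. It
provides, as one tested Python package:

- **a ground-truth simulator** for allopolyploid transcriptomes (two
  sister species, homeologue pairs at controlled percent identity,
  planted identical windows of 35–47 bp, heavily skewed log-normal
  expression, 75 bp reads with a late-cycle error "knee") plus FASTQ and
  truth-table output;
- **read QC**: trimming to the longest run of bases at or above Q20 and
  the ≥30 bp length/pair-demotion rule;
- **a minimal de Bruijn assembler** over canonical k-mers with a
  branch-terminating (chimera-safe) unitig traversal, an automatic
  coverage-cutoff mode, and a full (k, c) grid sweep;
- **reference mapping**: seed-and-extend contig alignment against a
  combined two-species CDS library (80% identity floor, longest-hit
  rule), complete-transcript calls at ≥95% reference coverage,
  bounded-mismatch (0–3) read mapping, and RPKM quantification
  `RPKM_X = 10^6 · M_X / (M_A · L_X)` with `L_X` in kilobases;
- **merging and classification**: pooling of contigs covering >55% of a
  reference, greedy CAP3-style overlap merging (≥40 bp at ≥98%
  identity), homeologue/orthologue/paralogue calls at the 95% identity
  threshold, and a truth-based chimera audit;
- **evaluation**: N50/N90 and length-class metrics, the pairwise
  assembly-overlap statistic `|A∩B| / (|A|+|B|) / 0.5`, per-gene
  (k, c)-success profiles, and the expression-vs-parameter-robustness
  correlation with the RPKM > 1000 exclusion.

## Worked example

```python
from alloasm import SimulationConfig, overlap_statistic, run_study

cfg = SimulationConfig(
    n_families=12, n_reads=12_000,
    homeologue_identity_range=(0.88, 0.92),
    expression_log_sd=1.0, high_expression_fraction=0.0, seed=42,
)
study = run_study(cfg, k_values=[31, 41], cutoff_values=[2, 3])

for (k, c), complete in sorted(study.complete_by_cell.items()):
    print(f"k={k} cutoff={c}: {len(study.grid[(k, c)].contigs):3d} contigs, "
          f"{len(complete):2d} complete transcripts")
print("overlap(41/2 vs 41/3):",
      round(100 * overlap_statistic(study.complete_by_cell[(41, 2)],
                                    study.complete_by_cell[(41, 3)])), "%")
print("chimera rate:", study.chimera_rate,
      f"({len(study.chimera_report)} supercontigs audited)")
```

prints

```
k=31 cutoff=2:  57 contigs,  2 complete transcripts
k=31 cutoff=3:  54 contigs,  1 complete transcripts
k=41 cutoff=2:  53 contigs,  8 complete transcripts
k=41 cutoff=3:  40 contigs, 10 complete transcripts
overlap(41/2 vs 41/3): 78 %
chimera rate: 0.0 (20 supercontigs audited)
```

The pattern is the study's central observation in miniature: at k=31
many homeologue pairs share identical runs of ≥31 bp, so traversal stops
at the resulting branches and few transcripts complete; at k=41 most
shared runs are shorter than k and completeness jumps. Adjacent grid
cells recover largely overlapping — but not identical — transcript sets,
and the branch-terminating traversal produces no chimeric supercontig
(verified against the simulator's ground truth).

A command-line interface mirrors the main steps (`alloasm simulate`,
`trim`, `assemble`, `sweep`, `map`, `express`, `evaluate`, `compare`);
see `alloasm --help`.

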