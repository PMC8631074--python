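# File schemas

All tabular files are TSV (UTF-8, '.' decimal); CSV is accepted on read.
Lines starting with `#` are provenance/comment headers. Row numbers in
error reports are 1-based data rows (header excluded).

## droplet_measurements.tsv

One row per extended droplet.

| column | unit | meaning |
| --- | --- | --- |
| droplet_id | — | unique droplet label |
| DL | um | suspended droplet length (parallel to support line) |
| DW | um | suspended droplet width |
| flattened_droplet_area | um^2 | area of the flattened droplet |
| flattened_core_area | um^2 | area of the flattened adhesive core |
| fiber_count | — | fibers in the support line |
| fiber_diameter | um | single-fiber diameter |
| fiber_modulus | MPa | fiber elastic modulus |
| span | um | support spacing (default 4800) |
| L_0 ... L_100 | um | droplet length at 0,20,...,100% of time to pull-off |
| theta_0 ... theta_100 | degrees | support-line deflection at each interval |

## lfq.tsv (long format)

One row per protein x sample.

| column | meaning |
| --- | --- |
| protein_id | protein or protein-cluster id (unique per protein) |
| sample_id | sample label |
| sample_type | `GlueFiber` or `Fiber` |
| run | MS run label (1 or 2) |
| lfq | label-free quantification value, >= 0 (0 = not quantified) |
| score | per-run search score for the protein |
| ptm_modified | optional 0/1: PTM evidence in this sample |
| ptm_score | optional: protein score in the PTM search |

## ptm_peptides.tsv

One row per peptide observation in one sample: `peptide_id`, `sample_id`,
`sample_type`, `glycosylated` (bool), `phosphorylated` (bool).

## gland_tpm.tsv

`transcript_id` plus one numeric TPM column per silk gland type.

## Result files

`material_properties.tsv`, `enrichment_results.tsv`, `ptm_report.tsv`,
`ptm_odds_ratios.tsv`, `sequence_properties.tsv`, `gland_percentages.tsv`
all start with `# config_hash=...` and `# seed=...` provenance lines.
`sample_dendrogram.nwk` is a newick serialization of the average-linkage
tree over one-minus-Spearman sample distances.
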