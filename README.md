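# truncalis

Analysis pipeline for multi-region tumor biopsies (MRTB): given per-biopsy
somatic variant tables from spatially separated cores of one lesion, it

- classifies variants as **truncal** (all analyzed biopsies), **branch**
  (more than one but not all) or **private** (exactly one), and reports
  mutational load and diversity;
- runs a **biopsy-subset saturation analysis**: for every subset size *k*
  of a patient's *b* biopsies it averages the number of unique variants,
  putative truncal variants (PTV, present in all *k* chosen biopsies) and
  the PPV (truncal count over subset PTV count) over all C(b, k) subsets,
  and determines the minimum number of biopsies via paired Wilcoxon
  signed-rank tests across patients;
- builds per-patient **parsimony phylogenies** (exhaustive Fitch search,
  germline outgroup, mutation-count branch lengths, Newick output);
- predicts truncal status **from a single biopsy** by thresholding allele
  frequency (AF) or cancer cell fraction (CCF, closed-form estimate from
  AF, purity, copy number and multiplicity), grid-searching the best
  threshold against the multi-biopsy ground truth;
- evaluates truncal-directed therapy with **PFS ratios** (therapy PFS over
  immediately-prior-therapy PFS; ratio ≥ 1.3 = clinical benefit);
- ships a **synthetic cohort generator** with known clonal structure
  (truncal clone, shared subclones, private subclones; binomial read
  sampling at configurable depth and purity) so every stage is testable
  without sequencing data.

## Input formats

- **Variants**: MAF-like TSV with columns `patient_id, biopsy_id, gene,
  chrom, pos, ref, alt, alt_count, ref_count` plus optional
  `variant_class` / `is_nss`; unknown columns are kept as annotations.
  Coordinates are 1-based; variant identity is `(chrom, pos, ref, alt)`.
- **Samples**: TSV with `patient_id, biopsy_id` and optional
  `dna_concentration` (biopsies under 4 ng/µL fail QC; patients with
  fewer than two passing biopsies are excluded from clonality analysis).
- **Panels**: plain text, one gene symbol per line (uppercased; no alias
  resolution).
- **Clinical**: TSV with `patient_id, pfs_prior_months, pfs_tdt_months`.
- **Config**: YAML key/value file mirroring `PipelineConfig` (QC cutoff,
  AF grid 0.01–0.55, CCF grid 0.90–1.00, benefit threshold 1.3, alpha).

## CLI

```sh
truncalis simulate --seed 7 --out sim/              # synthetic cohort
truncalis run --variants sim/variants.tsv --samples sim/samples.tsv \
              --clinical clin.tsv --out results/    # full pipeline
truncalis clonality  --variants V.tsv --samples S.tsv --out DIR
truncalis saturation --variants V.tsv --samples S.tsv --out DIR
truncalis sweep      --variants V.tsv --samples S.tsv --metric AF --out DIR
truncalis tree       --variants V.tsv --samples S.tsv --out DIR
truncalis pfs        --clinical C.tsv --out DIR
```

All commands accept `--panel P.txt` to restrict variants to a gene panel
and `--config cfg.yml`. Outputs are TSV/JSON; trees are Newick with the
germline leaf labeled `GL`.

## Notes and conventions

- Presence trusts the upstream caller's emission (`min_alt_reads`
  defaults to 0 and exists only as an explicit knob).
- Threshold comparisons are inclusive (`value >= t`); threshold ties
  resolve to the smallest grid value; both recorded in sweep metadata.
- Diversity is the mean ± sd of pairwise absolute per-biopsy load
  differences (interpretive convention).
- Reported PFS ratios are rounded half-away-from-zero to 3 significant
  figures; benefit calls and medians use the unrounded ratio.
- The exhaustive tree search is bounded at 8 tumor leaves; character
  changes are placed rootward when the minimum-cost assignment is
  ambiguous, and the per-edge TSV makes the assignment auditable.
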