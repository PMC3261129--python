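# ionmut

Analysis toolkit for heavy-ion mutagenesis screens in plants:

- **dosimetry** — convert between absorbed dose (Gy), LET (keV/μm) and
  particle fluence per cell-nucleus area (default 100 μm², unit-density
  water target), using 1 keV = 1.602×10⁻¹⁶ J.
- **junctions** — infer the single mutation event (substitution, deletion,
  insertion) separating a wild-type/mutant amplicon pair; report event
  size, left-aligned canonical placement, the placement-ambiguity interval
  and junction microhomology; measure microhomology of partially printed
  deletion junctions; classify rearrangement breakpoint reads into
  microhomology / blunt / filler joints with breakpoint-deletion sizes.
- **spectrum** — classify mutations into small alterations (< 100 bp,
  strict) vs rearrangements, tally transitions/transversions, and compute
  per-mil mutation frequencies from screening cohorts with exact
  Clopper–Pearson intervals, conditional-exact frequency ratios and
  Fisher tests (the intervals/tests are labelled methodological additions).
- **simulate** — synthetic amplicon pairs with planted events whose
  realized microhomology is re-measured by brute-force enumeration,
  synthetic translocation junctions, and binomially sampled cohorts, for
  closed-loop testing of every stage.
- **io / cli** — FASTA and TSV readers/writers (catalog positions in
  `Chr.4: 5,724,273-74` notation, truncated range ends expanded by
  digit-prefix substitution), packaged reference fixtures, a minimal VCF
  writer, and the `ionmut` command-line interface.

Reference fixtures (the published mutation catalog, junction sequence
pairs, partial junctions and screening counts) ship with the package under
`ionmut/data/` and load via `ionmut.io.load_*`.

## CLI

```bash
# dose -> particle fluence (and back with --fluence)
ionmut dosimetry --let 30.0 --dose 400 --json

# call mutation events from a pair catalog and partial junctions
ionmut analyze --pairs pairs.tsv --partials partials.tsv --out out/

# spectrum summary + frequency table from a catalog and cohort counts
ionmut spectrum --catalog catalog.tsv --cohorts cohorts.tsv --out out/

# synthetic dataset with a truth table
ionmut simulate --n 200 --seed 42 --out dataset/

# full pipeline from a YAML config
ionmut run --config config.yaml
```

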