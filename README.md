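# iespipe

Retention scoring and excision-error analysis of TA-bounded Internal
Eliminated Sequences (IESs), driven by a seeded simulator of paired
germline ("MAC+IES") / somatic ("MAC") genomes so every stage is testable
without external data.

In ciliates such as *Paramecium*, tens of thousands of short germline-limited
IESs are precisely excised during somatic genome development. Each IES is
flanked by a TA dinucleotide at both ends, a single TA remains at the
excision junction, IES ends carry a degenerate `5'-TAYAGYNR-3'` consensus,
and IES lengths follow a periodic (~10 bp) distribution with a 26 bp minimum
and a depleted 36–37 bp peak. This package implements the genome-wide
analyses built on those facts:

- **`iespipe.simulate`** — generates germline/somatic genome pairs with
  annotated IESs (TA-anchored, periodic lengths, end consensus), molecule
  populations with planted retention fractions, erroneous TA-to-TA excision
  junctions (configurable class mixture and boundary-shift spectrum),
  old-MAC contamination and a parental sample carrying pre-existing errors,
  plus full ground truth. Deterministic under a seed.
- **`iespipe.mapper`** — deterministic seed-and-extend classification of
  reads as IES+ boundary support, IES− junction support, alternative
  TA-bounded deletions (split-read detection with micro-homology
  normalization), or uninformative. Includes an optional SAM ingestion path.
- **`iespipe.retention`** — per-boundary retained fractions, IES retention
  scores (IRS = mean of the two boundary scores), and retention calls
  against a control sample (one-sided Fisher exact per boundary,
  Benjamini–Hochberg across boundaries).
- **`iespipe.errors`** — excision-event taxonomy (correct / partial internal
  / partial external / internal / external / overlapping / unmatched), one
  count per distinct junction, de novo accounting by parental subtraction
  with per-million-read normalization, boundary-shift spectra and
  error-prone fractions per IRS stratum.
- **`iespipe.analyses`** — IRS histograms (0.025 bins), excised-set
  overlaps, Mann–Whitney length comparisons (exact enumeration for small
  samples), size-peak fractions, end-motif PWMs and internal-TA
  availability.
- **`iespipe.cli`** — `simulate`, `map`, `retention`, `errors`, `report`
  and `run-all` subcommands over plain-text interchange formats (FASTA,
  FASTQ, GFF3, TSV with `# key=value` metadata).

## Quick start

```sh
iespipe run-all --config configs/demo.yaml --seed 11 --out-dir demo_out
```

This simulates genomes and three read sets (autogamous sample, parental
vegetative sample, fully-excising control), maps them, computes retention
calls against the control, classifies and summarizes excision errors with
de novo subtraction, and writes a TSV/JSON report bundle under
`demo_out/report/`. Stages can be re-run individually from their persisted
inputs; identical configs and seeds give byte-identical outputs.

Coordinate conventions: IES intervals are 0-based half-open `[start, end)`
on the germline, starting with the boundary TA, with the retained TA copy
at `[end, end+2)` (GFF3 output is 1-based inclusive). Reported deletion
intervals are normalized within their TA direct-repeat micro-homology to
the representation matching this convention.

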