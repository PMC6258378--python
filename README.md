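# svjunction

Nucleotide-level characterization of structural-variant breakpoint junctions
(BPJs) and downstream complex-rearrangement analytics for clustered germline
CNVs:

* **Junction characterization** — split reads bridging a candidate junction
  are clustered, assembled into a consensus (star alignment + greedy overlap
  merging, majority vote), re-mapped with a built-in exact-seed
  anchor-and-extend aligner, and resolved into junction records carrying
  microhomology (shift-ambiguity definition, left-aligned placement) and an
  insertion decomposition into templated (sourced within ±100 nt of the
  junction, either strand) and non-templated blocks, plus repeat-element
  annotation and junction-proximal novel-SNV detection.
* **Descriptor grammar** — parser/serializer for HGVS-like complex
  rearrangement descriptors (`g.[…del;…inv;…delins[…];…]`, nested payloads,
  `pter`/`qter`, `?` uncertainty), derivative-structure construction, and
  tokenized copy-number/orientation pattern strings (`DEL-INV-DEL`,
  `DUPinv-N-DUP`, …).
* **Derivative reconstruction** — fragment graphs from junctions +
  copy-number segments, exhaustive enumeration of terminus-to-terminus
  derivative structures, tandem/interspersed duplication-architecture calls,
  and junction equivalence comparison across cases.
* **Mechanism signatures** — per-junction repair-pathway flags (blunt/short-MH
  NHEJ, MMEJ, Polθ-type alt-NHEJ inserts, replicative microhomology,
  Alu-/LINE-mediated), a breakage-fusion-bridge / ring-attempt detector
  (terminal inverted duplication replacing the opposite terminal deletion),
  case-level mechanism suggestions (chromothripsis / chromoanasynthesis /
  ambiguous) with an explicit override table for expert judgment, and cohort
  summary statistics.
* **Rearrangement simulator** — synthetic references, planted rearrangements
  with exactly engineered junction chemistry (blunt, microhomology 1–40 bp,
  templated/non-templated inserts), and paired-end reads with analytically
  computed split alignments (SAM), so everything is testable hermetically.
* **Fixtures** — a 21-case cohort table bundle (83 junction records, CMA
  ISCN strings, rearrangement descriptors in raw/clean/normalized forms,
  CMA/WGS pattern strings, mechanism labels and overrides) shipped as
  package data.

## Command line

```sh
# parse a descriptor and derive its pattern string
svjunction parse-descriptor "NC_000017.10:g.[2220422_2484969del;2484970_2617882inv;2617882_2649613del]"

# plant a rearrangement and emit FASTA/FASTQ/SAM + truth tables
svjunction --seed 7 simulate --plan deletion --mh 5 --out-dir sim/

# characterize junctions from alignments
svjunction characterize --sam sim/alignments.sam --reference sim/reference.fa \
    --out-prefix out/junctions

# reconstruct candidate derivative structures from junctions + copy number
svjunction reconstruct --junctions out/junctions.json --cn sim/truth_cn.tsv \
    --span 1-8000 --out-prefix out/rec

# score signatures and suggest a mechanism
svjunction classify --junctions out/junctions.json --group deletions_only

# cohort statistics / bundled tables
svjunction summarize
svjunction fixtures --table 2
```

Global flags: `--seed`, `--config` (YAML with `signature:` /`library:`
sections overriding `SignatureConfig` / `LibraryConfig` defaults),
`--log-level`, `--strict`.

## Layout

```
src/svjunction/
  core.py          shared types, coordinates, sequence utilities, FASTA
  descriptors.py   descriptor grammar, patterns, group classification, ISCN
  characterize.py  split reads -> consensus -> junction records (+MH, inserts,
                   repeats, SNVs); built-in seed-and-extend aligner
  reconstruct.py   fragment graphs, structure enumeration, duplication calls
  mechanisms.py    junction signatures, BFB detector, case calls, summaries
  simulate.py      references, planted chemistry, read/alignment simulation
  io/              SAM, VCF (BND), repeat tracks, tables, bundled fixtures
  cli.py           command-line interface
tests/             unit + property + acceptance suites
scripts/acceptance.py
```

Coordinates are 1-based inclusive throughout; junction sides carry their own
orientation (`+` forward, `-` reverse-complement) and junctions are
canonicalized by left-alignment across microhomology tracts.
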