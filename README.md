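# riboevo

Analysis pipeline for the structural evolution of an RNA polymerase
ribozyme: per-position fidelity of ribozyme-synthesized RNA from deep
sequencing, round-by-round tracking of sequence clusters in an evolving
population, secondary-structure covariation and in-line probing
quantitation, and kinetic model fitting. A seeded synthetic-data generator
produces every input with known ground truth, so the whole pipeline runs
and is tested without any external download.

## Who this is for

Groups doing in vitro evolution of polymerase ribozymes (and nucleic-acid
enzymes generally) who need to answer, from sequencing reads, gel band
tables, and time courses:

* **How accurately does the ribozyme copy its template?** Product reads are
  aligned to the reference template; every aligned column is classified as
  match, mismatch (by incorporated base), deletion, or insertion per
  template position. The headline statistic is the average per-nucleotide
  fidelity

  `fidelity = Σ matches / Σ (matches + mismatches + deletions)`

  (coverage-weighted; insertions live on inter-position junctions and are
  reported as a separate rate). The mutation spectrum and the distribution
  of Levenshtein distances from the reference are reported alongside.
* **Which sequence variants rose and fell across evolution rounds?** Reads
  are quality-filtered (length > 150 nt, mean Phred > 33), trimmed to the
  region spanning the P7 and P8 stems (reference nucleotides 9–17 and
  83–95), clustered at 100% identity with two nucleotides of terminal slack
  (cd-hit-est `-c 1.0 -U 2 -S 2` semantics), merged when biologically
  equivalent, and tracked as a cluster-by-round frequency matrix. Paired
  5′/3′ strand variants are checked for correlated trajectories.
* **Which secondary structure do the data support?** Declarative structure
  models (the ancestral P7 stem-loop arrangement vs. the evolved P7+P8
  pseudoknot) are scored against sequence variants (Watson–Crick pair
  counts, disruptive/compensatory mutation verdicts) and against in-line
  probing intensities (background-corrected, scaled to the most-cleaved
  position, summarized as a pairedness-vs-protection correlation).
* **How fast is the reaction?** Time courses are fit to
  `F(t) = A_b + A_s·(1 − e^(−k_obs·t))` (single exponential rise to maximum
  with an initial burst phase), to linear initial rates (nt·min⁻¹), and to
  linear ligation rates (hr⁻¹), with fold rate accelerations at a chosen
  number of significant figures.

## Worked example

Simulate 2,000 product reads of the 33-nt hammerhead fixture at a uniform
8.3% per-position substitution rate, then run the fidelity pipeline:

```bash
riboevo simulate products --seed 7 --n 2000 --sub-rate 0.083 --out demo
riboevo fidelity --reads demo/reads.fq --ref demo/ref.fa \
    --condition "200 mM Mg2+" --out demo/fid
```

which prints

```json
{"average_fidelity": 0.9198387683355558, "condition": "200 mM Mg2+",
 "insertion_rate": 0.0002879136865074554, "mean_levenshtein": 2.6585,
 "n_reads": 2000, "wobble_fraction": 0.15590073877628338}
```

Reading the numbers: the estimated average fidelity (92.0%) recovers the
configured 91.7% truth to within sampling error at this read depth; the
mean Levenshtein distance of 2.66 edits per 33-nt read is consistent with
that error rate; the wobble fraction is the share of mismatches at
wobble-capable template positions (U read as G, G read as U) — here the
generator used a uniform mismatch spectrum, so it simply reflects template
composition. The small nonzero insertion rate on substitution-only input
is the aligner occasionally preferring an indel-pair reinterpretation of
clustered substitutions (see `docs/methods.md`).

The same executable exposes `track` (cluster frequencies across rounds),
`stem` (Watson–Crick pair counts for a stem), `probe` (in-line probing
normalization and structure concordance), `kinetics` (model fits), and
`simulate` for all synthetic inputs. Every run writes a manifest JSON with
checksums; identical configuration and seed reproduce identical outputs.

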