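# snvhmm

SNV calling from pileup text with a quality-aware, 3-state hidden Markov
model. Per-position genotypes (aa / ab / bb) are the hidden states of a
discrete HMM over consecutive covered sites; the emission model is a
generalized binomial over the site's reads in which each read's
contribution blends its Phred-scaled mapping quality, base quality and the
state's reference-allele frequency. Parameters are trained by Baum-Welch
(forward–backward for the initial distribution and transitions, a damped
Newton step for the per-state allele frequencies) and genotypes are decoded
with Viterbi. Sites decoded ab or bb that reach the minimum valid coverage
(MVC) are reported as SNVs.

## Layout

| module | purpose |
| --- | --- |
| `snvhmm.pileup_io` | samtools/Maq pileup parsing, Phred decoding, MQ/BQ filtering, top-2 allele reduction |
| `snvhmm.hmm_core` | emission model, prior-seeded initialization, scaled forward–backward, Baum-Welch + Newton, Viterbi, parameter serialization |
| `snvhmm.caller` | SNV calls gated by MVC; TSV and minimal VCFv4.2 output |
| `snvhmm.evaluation` | confusion tables, sensitivity/specificity/accuracy/F-score, threshold sweeps |
| `snvhmm.synthetic_data` | ground-truth pileup simulation under the same generative model |
| `snvhmm.cli` | `snvhmm` command with train / call / simulate / evaluate / sweep subcommands |

## CLI

```sh
# simulate 10X data with known truth
snvhmm simulate -o sim --n-sites 10000 --mean-depth 10 --seed 1

# self-train on the data itself, then call
snvhmm train sim.pileup -o params.txt --mq 0 --bq 0
snvhmm call sim.pileup -p params.txt --tsv calls.tsv --vcf calls.vcf --mvc 2

# or train+call in one step (no -p)
snvhmm call sim.pileup --tsv calls.tsv --mq 50 --bq 20 --mvc 4

# score against truth, sweep thresholds
snvhmm evaluate calls.tsv sim.truth.tsv
snvhmm sweep sim.pileup sim.truth.tsv -o sweep.tsv --mvc-grid 1,2,3,4,5
```

Defaults mirror the reference setting: `--mq 50 --bq 20 --mvc 4`. A
moderate MVC of roughly 15–25% of the mean sequencing depth is
recommended (best values were 2–5 at 10X and 6–9 at 40X). Pileup input is
the 6-column samtools layout, optionally with a 7th per-read
mapping-quality column; without it every read gets `--default-mq`
(Phred 30).

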