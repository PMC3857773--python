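# netmra

Master-regulator discovery from gene-expression data: mutual-information
network inference, regulon enrichment analysis, motif validation, and
survival stratification — with a ground-truthed synthetic-data generator so
the whole chain is testable end to end.

## Who this is for

Computational biologists asking "which transcription factors drive this
phenotype?" from expression cohorts. Given (i) expression matrices from two
disease cohorts, (ii) a TF list, and (iii) a case/control contrast, the
package reconstructs each TF's **regulon** (its set of transcriptional
targets), finds **master regulators (MRs)** — TFs whose regulons are
statistically enriched with the differential-expression signature of the
contrast — and then stress-tests them: an MR must replicate in both
networks, must *not* be an MR of the same signature in a control-tissue
network, and must not merely track a proliferation signature. Surviving MRs
can be validated by binding-motif enrichment in target-gene flanks and
assessed clinically with Kaplan–Meier / Cox survival analysis.

## The methods in brief

- **Network inference.** For every (TF, gene) pair, mutual information
  I(X;Y) = Σ p(x,y) log₂ p(x,y)/(p(x)p(y)) on an equal-frequency rank
  discretization (invariant to monotone normalization). Significance by a
  pooled permutation null with BH correction; indirect edges pruned by the
  **data processing inequality**: in a fully connected triple, the edge
  (a,c) is removed when MI(a,c) < min(MI(a,b), MI(b,c))·(1−ε).
- **Signature.** Welch t per gene on a two-group contrast, BH-adjusted,
  members filtered by FDR and |log₂FC|.
- **MRA.** One-sided hypergeometric test of the regulon/signature overlap k
  within the measured-gene universe, P(X ≥ k), BH across regulons;
  consensus = MRs significant in both disease networks; specificity filters
  subtract control-network and proliferation MRs.
- **Motif validation.** JASPAR PFM → log-odds PWM; scan threshold from the
  exact score distribution (dynamic programming) at scan p ≤ 1e-4; both
  strands scanned; regulon enrichment by resampling regulon-sized gene sets
  from the universe and a one-tailed z-test on the motif-carrier count
  (exact hypergeometric tail reported alongside).
- **Survival.** Kaplan–Meier with Greenwood variance, log-rank test,
  single-covariate Cox PH (Efron ties, damped Newton), and an optimal
  cutoff scan over the 25th–75th expression percentiles reporting both the
  nominal best-split p and a permutation-adjusted p.

## Worked example

`python examples/05_full_pipeline.py` generates a synthetic study (two
disease cohorts sharing one planted regulatory structure with driver TF000,
an independent control cohort, a 30+30 sample contrast shifting TF000 by
2 sd, E-box motif flanks, a survival cohort) and runs everything:

```
networks: a: 167 edges, b: 162 edges, control: 162 edges
signature: 21 differential genes
MRs network A: ['TF000']
MRs network B: ['TF000']
consensus: ['TF000'], control MRs: [], proliferation MRs: ['TF007']
final master regulators: ['TF000'] (planted driver: ['TF000'])
motif enrichment [a] TF000: z = 4.35, p = 2.19e-05
motif enrichment [b] TF000: z = 4.13, p = 5.40e-05
survival: Cox beta = 0.731, cutoff scan adjusted p = 0.0010
bundle checksum: 0fb4c6a79da8eaec... (identical on re-run)
```

Reading: both inferred networks call TF000 (and only TF000) a master
regulator of the contrast signature; the control network does not, and the
proliferation query flags only the designated proliferation TF — so TF000
survives the specificity filters, exactly matching the planted truth. Its
regulon carries the planted E-box motif far above chance in both networks,
and the survival covariate's fitted log hazard ratio (0.731) recovers the
simulated ln 2 ≈ 0.693.

The other examples (`examples/01`–`04`) demonstrate each stage in
isolation. Everything is also available from the shell:

```bash
netmra simulate --out study/ --seed 11
netmra run-all --config study/config.json --out results/
```

## Layout

```
src/netmra/      core.py (containers)  io.py (TSV/GMT/PFM/FASTA)
                 simulate.py (ground-truthed generators)
                 network.py (MI, permutation null, DPI)
                 signature.py  mra.py  motif.py  survival.py
                 pipeline.py (orchestration)  cli.py
examples/        one narrative script per capability
tests/           pytest suite (unit, property, acceptance)
docs/methods.md  models, assumptions, parameter choices, limitations
```
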