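# mirip

Quantification and cohort analysis of N6-methyladenosine (m6A) in microRNAs
from RIP-qPCR data, with composite biomarker scoring, survival statistics,
and consensus-motif scanning.

## The problem

A fraction of the copies of a mature miRNA can carry m6A, and the methylated
copies may lose their post-transcriptional repressor function: in
glioblastoma, adenosine methylation of miR-200b-3p releases its target XIAP
(an anti-apoptotic protein), lowers caspase-3/7 (DEVDase) activity, and marks
patients with shorter survival. The methylation level is set by the balance
of the writer METTL3 and the eraser FTO, whose activity depends on its
co-substrate α-ketoglutarate (αKG).

`mirip` implements the full computational path from raw qPCR threshold
cycles (Ct) to patient stratification:

1. **Quantification** (`mirip.quant`). All Ct arithmetic under the standard
   efficiency-2 model. Relative expression is the classic 2^-ΔΔCt fold
   change against a housekeeping RNA (SNORD6.1) and a reference tissue. The
   percent of miRNA copies carrying m6A is estimated from a three-condition
   RIP-qPCR (input, IgG control IP, anti-m6A IP) as IgG-subtracted
   percent-of-input:

       %m6A = 100 x max(0, 2^(c - Ct_m6A) - 2^(c - Ct_IgG)),
       c = Ct_input + log2(input fraction)

2. **Scoring and stratification** (`mirip.scoring`). The αFM score sums
   three median-dichotomized regulator states, +1 per marker in its
   methylation-promoting half (αKG ≤ median, FTO ≤ median, METTL3 > median),
   −1 otherwise, giving values in {−3, −1, +1, +3}. Patients split into
   three groups (group 1: %m6A > 10%; group 2: %m6A ≤ 10% and expression ≤
   median; group 3: the rest), and the poor-prognosis signature is
   "%m6A > 10% OR expression ≤ median". All thresholds are cohort-internal
   medians, so the rules are rank-based.

3. **Statistics** (`mirip.stats`). From-first-principles Pearson correlation
   (exact t-based two-sided p), equal-variance Student's t test,
   Kaplan-Meier product-limit estimator, and the two-group log-rank test.

4. **Motif scanning** (`mirip.motifs`). IUPAC-degenerate scanning of RNA
   sequences for m6A consensus motifs (UGAC, ADRA, and the METTL3/WTAP
   binding consensus GGACU), reporting all methylatable adenosines and their
   overlap with the miRNA seed region (positions 2–8). The mature
   hsa-miR-200b-3p sequence (miRBase MIMAT0000318) ships as a FASTA fixture.

5. **Synthetic cohorts** (`mirip.simulate`). Because no patient-level data
   are publicly deposited, a seeded generator produces GBM-like cohorts with
   the planted structure the analysis assumes — methylation driven on the
   logit scale by METTL3 (up) and FTO/αKG (down), XIAP coupled to the
   effective *unmethylated* miRNA dose, and exponential survival with a
   hazard ratio of 2.5 for the poor signature — plus matching Ct-level
   tables for end-to-end tests.

6. **Pipeline and CLI** (`mirip.pipeline`, `mirip.cli`). One reproducible
   run: quantify → score → stratify → test → survival, with a JSON report
   and per-patient CSV. Raw p-values only; no multiple-testing correction
   is applied, and the report metadata says so.

## Worked example

```python
>>> from mirip import percent_m6a, run_pipeline, GeneratorConfig
>>> percent_m6a(ct_input=20.0, ct_igg=28.0, ct_m6a=22.0)
24.609375
```

The anti-m6A IP recovered 2^-2 = 25% of input and the IgG control 2^-8 ≈
0.4%, so an estimated 24.6% of the miRNA copies are methylated.

```python
>>> report = run_pipeline(GeneratorConfig(seed=1))   # 32 synthetic patients
>>> c = report.correlations["pct_m6a_vs_mettl3_level"]
>>> print(f"r = {c['estimate']:.3f}, p = {c['p_value']:.4f}")
r = 0.375, p = 0.0344
>>> lr = report.survival["logrank_poor_vs_standard"]
>>> print(f"chi2 = {lr['statistic']:.3f}, p = {lr['p_value']:.4f}")
chi2 = 4.617, p = 0.0317
```

On this cohort the planted METTL3→methylation coupling is recovered as a
positive correlation significant at the 5% level, and the poor-signature
patients (high %m6A or expression-low) have significantly shorter survival.

The same run from the shell:

```bash
mirip simulate --n 32 --seed 1 --out cohort.csv
mirip analyze cohort.csv --report report.json --per-patient patients.csv
mirip scan-motifs src/mirip/data/hsa-miR-200b-3p.fa
```

The motif scan prints two ADRA consensus matches in the 3' half of
miR-200b-3p (BED-like: 0-based half-open coordinates, then the 1-based
adenosine positions):

```
hsa-miR-200b-3p	15	19	ADRA	16,19
hsa-miR-200b-3p	18	22	ADRA	19,22
```

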