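# phaseclear

Stage-transition mRNA clearance analysis for germ-cell RNA-seq and RIP-seq
count data.

During spermatogenesis, transcripts must be cleared on schedule as germ
cells move between stages (spermatogonia → pachytene spermatocytes →
spermatids). One clearance route is m6A-dependent: the reader protein
YTHDF2 binds N6-methyladenosine-marked mRNAs and accelerates their decay,
and in a germ-cell *Ythdf2* knockout these transcripts persist past their
stage. `phaseclear` implements the count-level analysis of that design for
anyone with gene-level count matrices from such an experiment — and, because
the interesting claims live in thresholded set intersections, it ships a
synthetic-data generator with planted ground truth so every rule can be
validated end to end.

The core rules, in the field's notation (all inequalities strict):

* **FPKM** from gene-level counts: `FPKM = counts · 1e9 / (N · L)` with
  per-sample depth `N` and effective length `L` (mass-conserving:
  Σ FPKM·L = 1e9 per sample).
* **RIP targets** per replicate: Input FPKM > 1 and IP/Input FPKM > 1.2;
  final targets = intersection across replicates.
* **DEGs** by a negative-binomial Wald test (median-of-ratios size factors,
  Var = μ + αμ² with trend-moderated dispersion, BH FDR):
  adjusted p < 0.05 and fold change > 1.5.
* **Delayed decay** = the four-way intersection: down-regulated across a
  stage transition in control ∧ m6A-marked at the earlier stage ∧ RIP
  target ∧ knockout fold change (later/earlier mean FPKM, pseudocount 0.1)
  > 1.2. Dropping the last criterion gives the *degraded* set.
* **Relative stability change** per gene:
  Δ = log2 FC(KO) − log2 FC(control), compared between gene groups with a
  Mann–Whitney U test (exact by enumeration for pooled n ≤ 12).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
dataset (4000 genes, 2 genotypes × 5 stages × 2 replicates × 3 assays):

```text
$ python analysis/01_simulate_dataset.py --seed 17
dataset: 4000 genes x 60 libraries (seed 17, digest 06720b2f3254)
planted class composition:
            constitutive: 2400
                m6a_only: 400
          cleared_target: 400
             target_only: 400
    persistent_nontarget: 400

$ python analysis/03_call_rip_targets.py
replicate 1: 849 targets
replicate 2: 825 targets
final targets (intersection): 796; IP replicate Spearman rho = 0.946

$ python analysis/04_differential_expression.py
control DSG->PS: 1417 down-regulated, 595 up-regulated genes (FDR<0.05, FC>1.5)

$ python analysis/05_classify_delayed_decay.py
degraded m6A-marked targets: 333
delayed decay in knockout (KO FC>1.2): 298

$ python analysis/06_stability_report.py
stability-change shift (m6A+target vs other, 4000 genes): U=1339470,
two-sided Mann-Whitney p=4.85e-181
recovery vs planted truth: sensitivity=0.745, FDP=0.000
down DEGs both bound and m6A-marked: 333/1417 = 23.5%
```

Reading: of 400 planted cleared-target genes, 298 delayed-decay calls are
made with zero false discoveries; bound + marked transcripts shift strongly
rightward in the stability-change distribution (they persist in the
knockout). Sensitivity sits near 0.75 by construction of the planted
conditions — the decomposition is in `docs/methods.md`.

The same steps are available as a CLI (`phaseclear simulate | fpkm |
rip-call | de | classify | report`), each command a thin wrapper over the
library in `src/phaseclear/`.

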