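# Methods

## Model and assumptions

The pipeline treats ectopic expression detection as two nested outlier
problems on a gene × sample intensity matrix.

**Atlas stage.** For each gene, the somatic tissues of a reference atlas
define a null location/scale: the per-gene threshold is the mean of the
somatic *tissue means* plus `k_atlas` times their sample SD (n−1
denominator). Tissue means — not raw samples — are the statistical units,
because the design is phrased over a panel of adult somatic tissues (112 in
the emulated setting) and because averaging within tissues first prevents
unevenly replicated tissues from dominating the SD. A gene is *predominant*
in a target class (germline, placenta, embryonic stem) when its class mean
(mean of the class's tissue means) strictly exceeds this threshold; it is
*restricted* when every non-target tissue mean is at or below a detection
floor while at least one target tissue mean is above it. Restricted implies
a stronger claim than predominant and takes precedence when both hold. A
gene silent everywhere is unrestricted: "restricted to" a compartment
requires presence in it.

**Cohort stage.** The control samples of the case/control cohort play the
same role per gene: `τ(g) = mean + k_control · max(SD, ε)`, and a case cell
is called ectopically activated when strictly above `τ(g)`. Only the
atlas-flagged candidate genes are tested (an `--all-genes` escape hatch
exists for exploration). No multiple-testing correction is applied by
design: the candidate genes are epigenetically locked in somatic tissue, so
the biological prior is strongly asymmetric, and the calling rule is
reported together with its exact null calibration instead (below).

**Assumptions.** Intensities are approximately Gaussian on the log2 scale
within a tissue or condition (log-normal intensities); control and case
samples are exchangeable under the null; genes are treated independently.

## Null calibration of the mean + k·SD rule

For `n` i.i.d. Gaussian controls and an independent null case cell,
`(X − X̄) / (S·√(1+1/n))` follows a t distribution with `n−1` degrees of
freedom, so the exact per-cell false-call rate is

    p(n) = P( t_{n−1} > k / √(1 + 1/n) )

which is ≈ 6.1% at n = 3, k = 3 and converges to Φ(−k) ≈ 0.00135 as
n → ∞. The small-n rate is a property of the published rule, not a defect
of the implementation; the package surfaces it (`calibration_experiment`)
rather than hiding it. Tests assert the empirical rate of the actual
calling code against these closed forms within 3 Monte-Carlo SEs.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `k_atlas` | 3 | SDs | the published multiplier of the atlas rule |
| `k_control` | 3 | SDs | the published multiplier of the detection rule |
| `detection_floor` | 25th percentile of atlas values | working scale | data-driven silence cutoff; no operational definition of "silent" is published, and an absolute override is accepted |
| `epsilon` | 1% of median control value | working scale | pseudo-SD floor; keeps τ strictly above the control mean when controls are (near-)constant, where otherwise any noise would flag the gene |
| working scale | log2(x+1) | — | microarray convention; mean+SD statistics are far more robust to intensity skew on the log scale; `--scale linear` computes on raw intensities |
| aggregation | all / any | — | genes activated in every case sample vs in at least one |

Ties between target classes (equal class means) break by the declared class
order (germline, placenta, embryonic stem), making output deterministic.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` defaults reproduce the study design: 112 somatic tissues,
3 control and 3 case samples, 30 planted restricted genes (germline or
placenta targets) and 40 planted predominant genes (cycling the three
classes) among 300 genes. Additive Gaussian noise (SD 0.5 log2 units) sits
on class-dependent means: baseline 5.0 for expressed somatic profiles,
0.0 for silent ones, 10.0 for restricted targets, baseline + 4 for
predominant targets; activations add `activation_shift` (default 10) noise
SDs to selected case cells. Three samples per tissue and two tissues per
target class are used so that both tissue-level SDs and class means are
proper averages. All draws come from one numpy PCG64 stream fixed by the
seed; identical config + seed reproduce byte-identical files.

The generator does **not** emulate probe-level artifacts, batch or platform
effects, correlated genes, or heavy-tailed noise. Passing tests therefore
demonstrate that the *algorithms* are implemented correctly and behave as
the closed-form theory predicts under their own assumptions — not that the
thresholds are well-calibrated on any particular real array platform.

## Numerical and design choices

- Strict `>` at both thresholds: a value exactly at threshold is not called.
- SDs always use the n−1 denominator; with 3 controls this matches the
  study's own setting.
- Duplicate probe ids collapse to the per-gene maximum at load time
  (conservative for presence calling); genes with missing cells are
  dropped; both counts are logged and recorded in the run summary, since
  downstream gene counts hinge on such silent filters.
- Concordance normalizes gene symbols by uppercasing/stripping only; alias
  resolution would require an annotation database and is deliberately out
  of scope, so cross-platform comparisons are exact-symbol matches.
- Requesting replication in more datasets than provided warns and returns
  the empty set rather than erroring (it is a well-defined, if vacuous,
  query).
- `run_pipeline` reads all inputs and computes every result before writing
  the first output file, so failed runs leave no partial artifacts.
- Floats are written with 6 significant digits; round-trips are exact at
  1e-6 relative tolerance.

## Problem sizes used by the test suite

Calibration checks use 200,000 null (gene, sample) draws per setting;
oracle-equivalence checks use 20 seeded 200-gene × 30-sample instances;
planted-recovery checks accumulate ≥ 10,000 planted activation events by
replicating 3-case cohorts over a fixed 112-somatic-tissue atlas. These
sizes give Monte-Carlo SEs small enough for 3-SE acceptance bands while
keeping a full run on one CPU to well under a minute per check.

## Known limitations

- The detection floor and pseudo-SD floor are data-driven defaults, not
  published constants; absolute overrides are provided and recorded in the
  run summary.
- With 3 controls the per-cell null call rate is ≈ 6%, so "any-case" gene
  sets contain an appreciable false-positive fraction by construction;
  "all-cases" sets are correspondingly stricter (≈ 0.02% per gene at 3
  cases under independence).
- Real-data headline gene counts depend on the specific atlas, platform
  and preprocessing used; they are not recoverable from synthetic data and
  are not claimed by this package.
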