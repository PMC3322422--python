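# Methods

## Sharing of a founder haplotype from unphased genotypes

A carrier's expansion chromosome descends from the founder chromosome, so
around the locus it carries the founder's risk alleles until recombination
has replaced the flank. With unphased data we only see per-site dosages of
the risk allele. The formal consistency rule is:

* dosage 1 or 2 — **consistent**: at least one phasing places a risk
  allele on the expansion chromosome, so the site cannot refute carriage;
* dosage 0 — **inconsistent**: no phasing can, so the site refutes;
* missing — neither refutes nor attests.

The per-sample sharing interval is the maximal contiguous run of
non-refuting markers containing the locus, grown outward from the two
markers flanking the locus until the first refuting site per side. Extents
are reported from the locus to the outermost *consistent* marker per side
(missing sites never extend evidence), in bp and in cM, with the locus'
genetic position interpolated linearly in bp between map anchors. "Full
sharing" means zero refuting sites panel-wide; "any sharing" means at
least one side has a consistent marker. Treating heterozygous sites as
always-consistent is a deliberate design choice — unphased data cannot do
better without statistical phasing, which is out of scope — and it makes
the measured extent an *upper* bound on the true founder segment: a
background chromosome can match by chance for several markers past the
true breakpoint (per-site chance consistency is 1 − (1 − f)² for
background risk-allele frequency f). Correctness of the run-finding is
pinned to a phase-enumeration oracle over all 2^h phasings on small
panels.

## The recombination clock

Under a star genealogy (every carrier connected to the founder by G
independent meioses) the flank survives to genetic distance x with
probability e^(−Gx); the per-side breakpoint is Exp(G) in Morgans. A panel
observes the breakpoint only between markers, so each side contributes an
interval-censored term:

* break between the run end at x_lo and the first refuting marker at
  x_hi: log(e^(−G·x_lo) − e^(−G·x_hi));
* shared to the panel edge: −G·x_end (right-censored);
* side with no consistent marker: interval (0, x_first].

Sides censored at 0 carry no information and are dropped; estimating with
*only* such sides is an error. The likelihood is scale-invariant
(x → cx, G → G/c) and, with all sides censored, monotone decreasing in G,
so the posterior mode sits on the prior floor — both properties are
asserted in tests.

Inference uses a uniform prior on (0, 2000] generations — weakly
informative, an order of magnitude beyond plausible founder ages for a
European disease mutation — and either exact grid quadrature (4000 points)
or a log-normal random-walk Metropolis sampler with a Hastings correction
for the multiplicative proposal. The step size is adapted during burn-in
toward ~30% acceptance and then frozen; the default schedule is 10 000
burn-in plus 10 000 retained iterations, and runs are bitwise reproducible
given a seed. Grid and MCMC medians agree to within 2% in tests. Posterior
medians and IQRs convert to years at a configurable generation time
(default 15 years).

**Model substitution.** Published founder-dating analyses of this kind
often use Bayesian linkage-disequilibrium mapping software with explicit
population-growth and sampling-proportion parameters. This package instead
implements the transparent star-genealogy interval-censored clock above:
the same decay physics without the demography. Consequences: (i) numerical
agreement with any particular published point estimate is not expected,
and the package's validation standard is *parameter recovery on synthetic
data* generated under the model's own assumptions (true age 100
generations, 262 carriers → posterior median within [80, 120] in ≥ 95% of
replicates); (ii) correlated genealogies (carriers sharing recent
ancestors) make flanks look longer than G independent meioses would — the
simulator's `correlated` mode demonstrates the resulting underestimate of
apparent decay, and an effective-sample-size deflation factor
(`ess_factor`, default 1 = off) is exposed to down-weight the likelihood.
A further known, quantified bias: because chance background consistency
extends measured runs beyond the true breakpoint, recovered ages sit a few
percent *below* truth at the default panel (median ≈ 90–100 at truth 100);
the bias grows with background risk-allele frequency.

## Penetrance

The product-limit estimator is computed on pooled risk sets with age at
onset in place of survival time; unaffected carriers leave the risk set at
their last known age. Conventions, stated because data of this kind rarely
state them: ties between an event and a censoring at the same age keep the
censored subject at risk for that event; quantile ages are the smallest
event age with P(t) ≥ q (left-continuity of the step function), flagged as
undefined when the curve plateaus below q; subjects missing the relevant
age are excluded listwise with a logged count. Greenwood's formula
Var[S] = S² Σ d/(n(n−d)) is reported per event age; note the *relative*
variance Σ d/(n(n−d)) is non-decreasing while the absolute variance can
fall in the tail as S² → 0, and the variance is set to 0 by convention
once S reaches 0. The k-sample log-rank test uses the full hypergeometric
covariance quadratic form (χ², k−1 df), matched to an independent survival
library to 1e-8 and calibrated for type-I error in simulation.

## Exact intervals and contingency tests

Clopper–Pearson bounds invert the binomial tail equations via beta
quantiles, with lower = 0 at k = 0 and upper = 1 at k = n; a bisection of
the binomial tails serves as an independent oracle in tests, and simulated
coverage at n = 50, p = 0.1 is ≥ 95% (the method is conservative by
construction). Pearson χ² uses Yates' continuity correction for 2×2 tables
by default — published p-values in this field are typically not exactly
recoverable from printed marginal counts because missing-data denominators
go unstated, so the correction choice is documented rather than fitted —
and flags expected counts below 5. No multiple-testing adjustment is
applied anywhere. Percentages are reported as fractions; rendering to one
decimal is left to the caller.

## The synthetic cohort generator

The generator is the package's test bed: it simulates exactly the process
the estimators assume, plus controlled violations.

* **Panel.** 42 markers over 2.4 Mb at 1 cM/Mb with the locus at
  mid-span, the two flanking tag SNPs 2.4 kb either side of the locus, and
  background risk-allele frequencies drawn U(0.05, 0.35). Three choices
  deserve comment. The genetic span (~1.2 cM per side) is wider than the
  core risk-haplotype region such studies print, because per-side break
  probability 1 − e^(−G·x_edge) governs information: at 100 generations a
  0.1 cM flank yields breaks on ~10% of sides and no usable dating signal
  at a few hundred carriers, whereas 1.2 cM yields ~70%. The tight
  flanking tags mirror association panels whose top markers bracket the
  causal variant, and make zero-length sharing (recombination within
  2.4 kb of the locus in *every* lineage side) effectively unobservable —
  so error-free founder cohorts reproduce universal partial sharing. The
  frequency range keeps the founder haplotype on the less common allele at
  each site, as founder risk haplotypes characteristically are; raising
  the range toward 0.5–0.8 makes unphased consistency uninformative and is
  useful only for stress-testing the chance-sharing bias.
* **Decay.** Per carrier and side, a breakpoint ~ Exp(G) (the minimum of
  G per-meiosis recombination distances); markers within the breakpoint
  keep the founder allele, markers beyond are redrawn from background, and
  the partner chromosome is background throughout. Background markers are
  independent (no background LD) — sufficient for testing refutation
  logic, but real panels have LD that lengthens chance sharing; this is a
  stated limitation of what passing tests show about real data.
  Missingness is applied i.i.d. at a configurable rate. True breakpoints
  go into the truth record, and their capped means are checked against the
  closed form E[min(Exp(G), x_edge)] = (1 − e^(−G·x_edge))/G.
* **Clinical layer.** Affected carriers draw onset from a normal
  truncated at 0 (default mean 56.8, SD 9.1 years — the reported carrier
  onset distribution in large ALS screens; truncation chosen over a
  log-normal for parameter transparency); ~1% of carriers (default 5/603)
  remain unaffected, censored uniformly on a configurable age range
  (40–75 default, explicit because real studies do not publish their
  healthy carriers' ages). Non-carrier patients draw onset at mean 58.7,
  SD 12.8. Sex, site-of-onset and FTD-presentation rates default to the
  carrier/non-carrier splits of published demographic tables. Repeat
  counts: expansions from a truncated normal above 30 (mean 1200, SD 500,
  the order of magnitude of true pathogenic expansions), wild-type below
  20 (mean 7, SD 3).
* **Strata.** With strata configured, carrier counts are binomial at each
  stratum's true rate, so frequency-table coverage can be tested against
  known truth.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: 262 carriers
for sharing/dating experiments (20 replicates for recovery), ~600 carriers
for penetrance, 1000–2000 replicates for oracle-equivalence and coverage
checks, grids of 4000 points for quadrature. Oracle equivalences are
asserted at 1e-12 (KM), 1e-9 (χ²), 1e-8 (log-rank), exact index equality
(sharing); stochastic recoveries at 3 SE (simulator calibration), ±1 year
(KM median, averaged over 20 replicates), [80, 120] generations (age
recovery). These sizes make every property estimable with comfortable
margins at desk scale.

## Known limitations

No statistical phasing or imputation; no background LD in the simulator;
no demographic (population-growth) model in the clock; no left-truncation
or covariate adjustment in penetrance; genotyping error is modelled as
missingness only. The indeterminate 20–30 repeat band is excluded from
carrier counts rather than resolved — resolving it needs assay information
the pipeline does not model.
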