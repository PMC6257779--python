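# Methods

## Model and inference procedure

The data model is a first-order linear dynamic network over $p$ genes: with
$x(t_k) \in \mathbb{R}^p$ the (log-)expression vector at the $k$-th retained
time point,

$$x(t_k) = c + A\,x(t_{k-1}) + \varepsilon_k,\qquad
\varepsilon_k \sim \mathcal{N}(0, \sigma^2 I),$$

and the regulatory structure is the support of $A$: $A_{ij} \neq 0$ means
gene $j$ regulates gene $i$ one lag ahead. Unrolled over time this is a
dynamic Bayesian network whose collapsed graph may contain cycles and
self-loops; the package excludes self-loops by default (a flag restores
them) because a lag-1 self-coefficient is confounded with autocorrelated
noise at these series lengths.

Structure learning is the dependence-testing route, in two stages:

1. **Screening.** For the ordered pair $j \to i$, every single conditioning
   gene $z \notin \{j\}$ (and $z \neq i$ when self-loops are off) defines a
   regression of gene $i$'s responses on an intercept, lagged $j$ and lagged
   $z$; the score $s_1(i,j)$ is the *maximum* over $z$ of the two-sided
   p-value of lagged $j$'s coefficient. Taking the worst case over single
   confounders makes the score deliberately conservative: under
   independence the max of p-values is stochastically larger than uniform,
   so the screen's false-positive rate at any cutoff is below nominal (a
   property the test suite checks by Monte-Carlo). With $p = 2$ genes no
   conditioner exists and the simple-regression p-value is used. Pairs with
   $s_1 \le \alpha_1$ become candidate edges.
2. **Pruning.** Per target, one joint OLS regression on all candidate
   parents; an edge survives iff its coefficient p-value is $\le \alpha_2$
   and inherits that p-value as its edge score. If a target has more
   candidate parents than $n-2$ (with $n$ the number of transitions), the
   worst-scored parents are dropped first, with a warning.

The estimator is ordinary least squares throughout (recorded in run
configs as `estimator: ols`); robust variants were considered out of scope.
Defaults $\alpha_1 = 0.5$ (permissive screen) and $\alpha_2 = 0.05$ (strict
prune) are exposed everywhere, since no universal values exist for these
thresholds — they trade sensitivity against precision and should be chosen
per study.

### Treatment of irregular sampling

Consecutive *retained* observations form unit-lag transitions regardless
of their hour labels: the gap between 8 h and 12 h counts the same as the
gap between 12 h and 13 h, and deleting a time point simply splices its
neighbours together. This is a deliberate modelling approximation, stated
prominently: it matches how short irregular time courses are analysed in
practice, it is what makes the deletion experiment well defined, and the
simulator makes the *same* approximation so that synthetic recovery
results are internally consistent. Interpolation or gap-aware weighting is
explicitly not attempted.

### Numerics

Screening runs $O(p^3)$ three-parameter regressions, so the implementation
vectorises them: predictors and responses are centred once, the
regressions reduce to $2\times2$ solves expressed with the Gram matrix of
centred lagged profiles, and p-values come from the $t$ survival function
with $n-3$ degrees of freedom. Zero-variance lagged predictors carry no
evidence and score 1 (with a logged warning) rather than erroring, which
keeps deletion sweeps running on degenerate subsets; collinear
conditioners are excluded from the max; an exactly-fit regression (zero
residual, e.g. noise-free synthetic data) yields p-value 0 for nonzero
coefficients and 1 for zero ones. The test suite pins every p-value to an
independent statsmodels OLS computation at 10 significant digits.

## Statistics panel

| statistic | graph used | definition |
|---|---|---|
| $K$ | directed | $\sum_v \mathrm{deg}(v)/N = 2R_n/N$ (total degree) |
| $Dia$ | directed | longest finite shortest-path length |
| $l$ | directed | mean shortest-path length over reachable ordered pairs |
| $E$ | directed | $\frac{1}{N(N-1)}\sum_{i\neq j} 1/d_{ij}$, $1/\infty = 0$ |
| $B_v$ | directed | $\sum_{i\neq v\neq j} g_{ivj}/g_{ij}$ (unnormalized) |
| $V_u$ | directed | $\max_i (E - E_i)/E$; 0 when $E = 0$ |
| $CC$ | projection | $3\cdot\text{triangles}/\text{connected triples}$ |
| $Ce$ | projection | $\sum_v (d_{\max} - d_v) / ((N-1)(N-2))$ |

Where the directed/undirected choice is genuinely open, path-based
statistics use the directed graph (regulation has direction) while the
triplet and centralization formulas use the undirected projection (they
are undirected constructs; the star graph then attains $Ce = 1$ under the
$(N-1)(N-2)$ normalization). Unreachable pairs are excluded from $l$ and
contribute 0 to $E$ — without this convention both are infinite on any
network with isolated genes. Networks with no finite path at all report
$Dia = l = 0$ with a `path_metrics_defined: False` flag rather than NaN.

Degree distributions are fit by least squares on
$(\log_{10} d, \log_{10}\,\mathrm{count}(d))$ over degrees $\ge 1$;
maximum-likelihood tail fitting is a non-goal — the $R^2$ of the log-log
line is used only to *rank* networks by how power-law-like they are.

## Deletion experiment and diversity score

`standard_design(T, pairs=...)` builds G0 + G1..GT (+ pair entries); each
entry deletes its time points, re-infers with identical thresholds, and
contributes one row to the statistics table. Entries retaining fewer than
5 time points (4 transitions — the minimum for the 3-parameter screening
regressions) are recorded as failed rather than aborting the sweep.

The relative diversity score $d = \sum_k |Q_k - \overline Q|/\overline Q$
is scale-invariant ($d(cQ) = d(Q)$ for $c>0$), which is why the $K$ and
$R_n$ columns of any sweep table must produce identical scores ($K$ is
exactly $2R_n/N$). It is undefined (error) for zero-mean columns; in
assembled tables such columns get NaN. The formula is isolated in one
function so alternative dispersion measures can be swapped in.

## Comparison conventions

Confusion counts run over the full ordered-pair universe, $p(p-1)$ pairs
without self-pairs (the default, matching the inference default) or $p^2$
with them; the choice affects only TN. Mismatched gene panels raise
rather than silently intersecting. Sensitivity, precision and F-measure
define 0/0 as 0 so sweep tables stay numeric; this is flagged in the type
documentation rather than silently assumed. Edge-overlap output reports
both the exact-$m$ and $\ge m$ occurrence curves; the "common
regulations" table lists exact-$m$ edges with their member and absent
network labels.

## Synthetic-data generator

The generator draws each allowed ordered pair as an edge independently
with probability `expected_edges / n_allowed` (realised counts are
binomial around the target), coefficients uniform on $\pm[lo, hi]$ with
zero excluded, rescales the matrix onto spectral radius 0.95 if needed,
and simulates from a standard-Gaussian initial state. Defaults chosen
once and held fixed:

* **Recovery conditions** — 20 genes, 40 expected regulations,
  $|a| \in [0.5, 1.0]$, noise sd 0.1, 50 time points: a regime where a
  correct implementation recovers structure well (median F ≥ 0.7) and a
  subtly wrong one does not.
* **Deletion-sweep conditions** — 50 genes, 50 expected regulations at
  the 11-point diurnal grid (0,1,2,4,8,12,13,14,16,20,24 h): edge density
  ~1 regulation/gene, mirroring the ~0.56 of the 800-gene/447-regulation
  Arabidopsis reconstruction while keeping nine-transition inference
  non-trivial. 10 seeds are averaged for the pair-vs-single deletion
  comparison; the problem sizes keep the full suite fast at desk scale.

What the generator does *not* emulate: microarray measurement error
structure (probe effects, saturation), non-Gaussian noise, unobserved
regulators, nonlinear or time-varying regulation, and any preprocessing
(normalisation, log-transformation) applied upstream of a real
expression matrix. Passing synthetic-recovery tests therefore shows the
estimator is correct *for its own model class*, not that real-data
reconstructions are accurate; the deletion-damage ordering (adjacent-pair
worse than single) is the qualitative behaviour expected to transfer.

The loader for real matrices applies no transformation; results on real
data depend on upstream preprocessing, which the file format cannot
record.

## Determinism

Every source of randomness is an explicit seed argument; there is no
global random state. The end-to-end `run` command writes a log without
timestamps and serialises floats with a fixed format, so reruns of the
same config are byte-identical — the property the pipeline test asserts.

## Known limitations

* Lag-1 only: regulation acting over two or more sampling intervals is
  mis-attributed or missed.
* The unit-lag treatment of irregular grids biases coefficient estimates
  when true dynamics are continuous-time.
* Worst-case-over-conditioners screening is conservative; weak hub
  regulators with many correlated partners can be screened out.
* With very short series (≤ 6 transitions) the per-target parent cap
  $n-2$ binds often, and pruning decisions depend on step-1 rank.
* The diversity score requires a nonzero mean and is unstable when the
  mean is near zero (e.g. a statistic that vanishes in most networks).
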