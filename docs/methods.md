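# Methods

## Model and procedure

Krippendorff's alpha measures agreement among any number of raters on a
common set of units, on nominal, ordinal, interval or ratio scales,
tolerating missing ratings. The implementation works from the
rates-by-units tally rather than pairwise coincidence tables: for each
unit u and observed category c it counts the raters n_uc assigning c to
u; category marginals n.c and the grand total n.. pool only units with
at least two ratings, because a lone rating can be paired with nothing.
Alpha is 1 − Do/De with

    Do = (n.. − 1) Σ_u [Σ_{c<k} n_uc n_uk δ²_ck] / (n_u. − 1),
    De = Σ_{c<k} n.c n.k δ²_ck,

the outer sum over units with n_u. ≥ 2. The (n.. − 1) factor is the
small-sample correction that makes chance-level raters score zero in
expectation; the null-calibration test verifies this empirically.

The difference function δ² is the only metric-dependent piece. The
ordinal form squares the count of pairable ratings lying between the
two ranks (half-weighting the endpoints), evaluated on the numeric
order of the observed values; unobserved intermediate integers have
zero marginal and so contribute nothing, which is why the category
universe can be restricted to observed pairable values. The ratio form
requires non-negative rates (a true zero); violations raise a typed
error rather than producing a silently meaningless number.

Numerics: counts are tallied exactly in integers; Do and De are
accumulated in floating point and the ratio Do/De is formed once at the
end, so the worked example reproduces its three printed decimals. The
full-precision alpha is kept in the result; rendering rounds to three
decimals. The quadratic forms use the symmetry and zero diagonal of the
δ² matrix (Σ_{c<k} x_c x_k δ² = xᵀΔx/2).

## Degenerate inputs

Two failure modes are distinguished. If no unit has two ratings there
is nothing to pair: a degenerate-data error. If De = 0 — every pairable
rating is the same single category — alpha is the indeterminate form
0/0; reporting 1 would overstate reliability, so a typed
undefined-alpha error is raised carrying the data summary and a flag
confirming the uniformity. For the implemented metrics De = 0 can only
occur with a single observed category (every off-diagonal δ² is
strictly positive when both marginals are), so De = 0 with Do > 0 is
unreachable and treated as an internal error.

## Bootstrap confidence intervals

Whole item rows are resampled with replacement, keeping the row count;
raters are never resampled, and each replicate uses its own observed
categories and marginals. Bounds are equal-tail empirical quantiles of
the replicate alphas with linear interpolation between order
statistics, making bounds bit-reproducible given the seed (a seed is
required; the CLI documents its default). A replicate consisting
entirely of identically-rated or unpairable rows is maximal-agreement
evidence and is scored alpha = 1, counted in `n_degenerate`; dropping
such replicates would bias the upper tail downward. If every replicate
degenerates, no interval exists and a typed error is raised.

On small panels the replicate distribution is discrete: on the bundled
12-unit example it has an atom at exactly 1 (resamples drawn solely
from unanimous rows, probability ≈ 0.03 per replicate) and a gap down
to ≈ 0.94. The upper bound of a 95% interval therefore alternates
between 1.000 and ≈ 0.94 across seeds depending on whether the atom
captures the top 2.5% of replicates — an inherent property of
percentile quantiles on atomic distributions, not a convergence issue.
The lower bound is stable to within a few hundredths across seeds.

Levels 90/95/99% and sizes 200/400/600/1000 mirror the menus of
point-and-click reliability tools; other values are accepted with a
warning to encourage comparable reporting.

## Interpretation bands

Banding follows Krippendorff's reporting conventions: ≥ 0.80
satisfactory, 0.67 ≤ α < 0.80 tentative, < 0.67 poor, with exact-value
annotations at 1 (perfect), 0 (chance) and below 0 (systematic
disagreement). The conventional thresholds overlap when stated as
rounded ranges, so bands are defined on the unrounded coefficient with
half-open intervals, making the mapping total on [−1, 1]; whether to
round before banding was an open choice and unrounded banding was
selected for determinism at the boundaries.

## File contract

Input is headerless delimited text, comma or semicolon, integer rates,
`NA` for missing. Exactly one delimiter must split every line into the
same number (≥ 2) of fields; tabs anywhere are an error, as are blank
interior lines, whitespace-padded tokens and decimal rates. Negative
integers are lexically accepted (strictness about scale belongs to the
metric, which rejects them for ratio data). A single trailing newline
and CRLF line endings are tolerated as file-system realities. A relaxed
mode trims whitespace and admits decimals for interval/ratio exports
from other tools; the strict contract is the default. The 500 KB limit
some web tools impose on uploads is a browser constraint and is not
enforced here.

## Synthetic panels

The generator follows a latent-truth copy model: each item draws a
latent category uniformly; each rater reports it with probability
`agreement`, otherwise an independent uniform category; cells are then
masked missing completely at random with probability `missing_rate`.
Defaults used in the test suite: 3 equiprobable categories and 4
raters (a typical coding-study panel), 2000 items × 50 replicates for
null calibration (agreement 0), 40 items × 100 replicates per level for
the monotonicity check at agreement ∈ {0, .25, .5, .75, 1}, and 50-item
panels with agreement 0.7 and 200-replicate bootstraps for the
200-panel coverage simulation, sized to keep the suite fast while
leaving Monte-Carlo error well inside the asserted tolerances.

The model yields a monotone link between the copy probability and
expected alpha and makes missingness ignorable by construction — which
is exactly what the property tests assert. It deliberately omits
rater-specific bias, ordinal-adjacent confusion and informative
missingness, so passing tests say nothing about robustness to those
features of real panels; they validate the estimator, not any claim
about real raters.

## Oracle

`pairwise_alpha_oracle` recomputes alpha by brute-force enumeration of
ordered rating pairs — within-unit pairs for Do (each unit's mean pair
disagreement weighted by its rating count), pooled pairs for De with
the (n.. − 1) small-sample structure — sharing no tally code with the
main path. Equality to 1e−12 on thousands of random matrices across
all four metrics is the package's primary correctness evidence; the
worked example's published coefficient is the external anchor.

## Known limitations

Only the four classical metrics are provided (no custom difference
functions, no Cohen/Fleiss kappa or ICC). Bootstrap intervals are
percentile-only (no BCa or jackknife), and on very small panels their
bounds inherit the discreteness described above. Category values must
be numeric; string labels should be recoded before input.
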