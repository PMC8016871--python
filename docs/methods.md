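# Methods

## Model structure

Two strategy arms are compared for a cohort entering with an acute minor
stroke or high-risk TIA (all patients start at mRS 0–2):

* **Genetic testing** — everyone is genotyped for CYP2C19 loss-of-function
  alleles. Non-carriers (weight 0.41) and carriers with ESRS ≥ 3 (0.22)
  receive clopidogrel–aspirin; carriers with ESRS < 3 (0.37) are switched
  to dipyridamole–aspirin. 90-day recurrence risks: 0.0717 / 0.0871 /
  0.0727 respectively.
* **No testing** — everyone receives clopidogrel–aspirin; pooled 90-day
  recurrence risk 0.082.

Within 90 days a patient faces mutually exclusive chance branches:
recurrent stroke (intracerebral hemorrhage with probability 0.0377,
otherwise ischemic), major extracranial hemorrhage (0.0108) or myocardial
infarction (0.0012); only recurrence changes disability. The arms' 90-day
distributions over the four mRS states are first-class inputs
(0.9506/0.0404/0.0054/0.0036 vs 0.9376/0.0527/0.0058/0.0039); a secondary
"derived" mode reconstructs them from the subgroup risks, the
early-recurrence fraction (90-day / one-year risk, e.g. 0.083/0.103 =
80.6 %), the hazard-ratio adjustment for the dipyridamole switch
(0.0932 × 0.78 = 0.0727) and the disability-rate formula
`(A·(B−C)/B)·(1−C)` (parenthesization selectable; the printed expression
is ambiguous, and neither reading reproduces the printed moderate
proportion exactly — hence the table mode is primary).

The 90-day survivors seed a Markov cohort model over 30 annual cycles.
Each cycle, each alive state faces, in order, on the residual mass:
recurrent stroke (probability 0.1219 × 1.017^(t−1), case fatality 0.1933,
survivors reallocated equally among the states of equal and greater
disability), major ECH (0.0038, fatality 0.06), MI (0.0085, fatality
0.15), and age-specific non-stroke death. Death is absorbing; ECH and MI
are temporary states that never change disability.

## Costs, utilities, discounting

All costs are 2019 CNY. The 90-day block books the test fee (genetic arm),
the proportion-weighted 90-day drug price (490.45 clopidogrel–aspirin,
504 dipyridamole–aspirin), and event hospitalizations: recurrences split
ischemic/ICH and by resulting band — mRS 0–2 (12,499.91 / 14,086.15) vs
mRS 3–6 (18,700.45 for both; the duplicated printed ICH row is read as the
mRS 3–6 row), ECH 9,125.97, MI 21,276.20. Each Markov cycle books annual
maintenance by band (mRS 0–2: 8,767.42; mRS 3–5: 13,850.50) for the alive
cohort plus the cycle's event hospitalizations; fatal recurrences are
costed at the mRS 3–6 price. Utilities: 0.75 / 0.39 / 0.20 / 0. Nonfatal
ECH and MI episodes (2 weeks, 30 days) multiply the state utility by the
episode utility (0.8, 0.84) for the episode duration — absolute
replacement would *raise* utility above the mRS 0–2 level, contradicting a
disutility; a replacement mode exists for comparison. Costs and outcomes
are discounted at 3 %/year, cycle *t* by (1+r)^−t; the 90-day block is
booked undiscounted at time 0.

**State-reward accrual.** Per-cycle state rewards (maintenance cost and
utility) accrue on the **start-of-cycle occupancy** by default — the
convention of stage rewards in the TreeAge-style software family this
model emulates; `state_accrual` can be set to `"end"` or `"mid"`
(half-cycle correction). The choice moves per-arm totals by ~5 % and the
incremental results by a few percent; start-of-cycle agrees best with the
published per-arm anchors.

## Mortality schedule and calibration

Only the endpoints of the age-specific non-stroke mortality schedule are
published (0.0089 → 0.1654 over the horizon). `generate_schedule`
interpolates between them — geometrically by default, since adult
all-cause mortality grows roughly exponentially with age — and a single
scale factor, clipped back into the published range, is the one free
quantity. `calibrate_schedule` fits it to the published per-arm lifetime
QALYs (5.1450 / 5.1140) by deterministic bounded 1-D search; QALYs only
are targeted (costs follow occupancy and are reported as residuals). At
defaults the fit is essentially exact on QALYs (residuals ±0.002 %, scale
3.687) and leaves per-arm costs ≈ 6 % low; the resulting 30-cycle schedule
ships as `data/mortality_schedule_default.csv` and is the package default.
Start age defaults to 62 (typical of the underlying trial population; the
schedule is indexed by cycle, so the age label does not alter rates).

## Sensitivity analyses

One-way analysis re-runs the full pipeline at each parameter's published
low and high (all else at base) and sorts by ICER spread. Fixed-tagged
parameters with a genuine range (the discount rates: costs 0.03–0.08,
outcomes ±20 %) are varied deterministically but excluded from
probabilistic sampling, the usual practice. The PSA draws every sampled
parameter independently from a triangular distribution over (low, base,
high) — the only family fully determined by the printed triples; the
published description of the distribution families is garbled, so the tag
is configurable per parameter (`normal`, `beta` implemented). The
no-testing arm's 90-day minor proportion has no published range; it
mirrors the genetic arm's absolute offsets (0.9260–0.9480 around 0.9376).
Holding it fixed would make the beneficial fraction 100 %, inconsistent
with the published 96.94 %, so it must have been varied. When a minor
proportion moves, the moderate state absorbs the change by default
(`p90_renormalization="moderate"`) — the published mechanism is explicitly
a minor ↔ moderate trade-off — with proportional rescaling selectable.
The mortality schedule is not resampled (its uncertainty is unpublished).

## Validation oracle

`run_microsim` replays the identical event logic — branch order,
reallocation rule, costing bands, disutility and accrual conventions,
discounting — for individual simulated patients (numpy vectorized) and
returns per-arm means with Monte-Carlo standard errors. Tests require the
cohort totals to sit within 3 SE of the microsimulation means at 200,000
individuals, for the defaults and for 20 randomized parameter sets, plus
a zero-variance degenerate case and a closed-form annuity limit (all
event rates zero) checked to 1e-9.

## Problem sizes

The shipped analyses use the published sizes throughout: 30 annual
cycles, 10,000 PSA iterations, 200,000 microsimulation individuals (a
size at which the Monte-Carlo SE resolves the between-arm differences).

## Reproduction quality and known limitations

With the calibrated schedule the model reproduces the published per-arm
QALYs exactly, per-arm costs within ~6 %, the incremental QALY gain
(0.0308 vs 0.031) and — less tightly — the incremental cost (566.69 vs
420.13). The ICER lands at 18.4k vs the published 13.55k CNY/QALY. Three
published results could not be reproduced more closely, for reasons that
are structural rather than parametric:

* Because both arms share all post-90-day dynamics, the between-arm
  occupancy difference is fixed by the 90-day seeds and decays under the
  common transition operator. This bounds the long-run cost saving per
  QALY gained near −13k CNY/QALY; the published base-case triple implies
  ≈ −17k. No mortality schedule or accrual convention closes that gap.
* The published one-way endpoints for the mRS 3–5 maintenance cost
  (4,961.67 at the low bound, 33,439.13 at the high) imply the ICER
  *rises* in that cost with a 5-fold asymmetric slope. The ICER is exactly
  linear in any cost parameter, and its slope in this one equals the
  genetic arm's excess discounted mRS 3–5 years — provably negative under
  shared dynamics. This model yields 41.3k / 8.6k: the same spread
  magnitude with the opposite, internally consistent, pairing.
* The published PSA fractions (2.59 % dominant, 95.71 % cost-effective)
  imply an incremental-cost spread of ≈ 216 CNY, while sampling the
  published mRS 3–5 cost range alone contributes ≈ 209; this model gives
  6.9 % / 91.5 %. The published OWSA slope for the same parameter would
  imply a dominant fraction near 16 % — the published base case, one-way
  and probabilistic results are not mutually consistent, so no single
  coherent implementation can match all of them.

Other limitations: the synthetic mortality schedule emulates only the
published endpoint range, not real life-table age structure; parameters
are sampled independently (no published correlations); genotyping
misclassification (accuracy parameter), treatment adherence and long-term
drug costs beyond the banded maintenance costs are not modelled. Passing
tests therefore demonstrate internal consistency with the published input
tables, not fidelity to patient-level trial data.
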