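# Methods

This note documents the models and procedures the package implements, the
numerical choices behind them, and what the synthetic-data tests do and do
not establish.

## 1. Interpausal units and canonicalisation

An interpausal unit (IPU) is one speaker's speech bounded by silences of
at least `min_pause_ms` (default 200 ms). Input annotations are trusted
for boundary placement (no audio is processed); canonicalisation only
enforces the definition: consecutive same-speaker units separated by
*less* than the threshold are merged, with the sub-threshold silence
becoming interior to the unit and labels concatenated. A pause of exactly
the threshold is a valid pause and is kept; a 1 ns guard keeps float
subtraction from flipping that boundary case. Merging is a single
left-to-right pass, which is equivalent to iterating to fixpoint (verified
against a fixpoint oracle in the tests). Same-speaker overlap is an error:
no annotation pipeline should produce it, so it is surfaced, not repaired.

Conventions inherited from the annotation style: audible in-breaths and
clicks are already labelled as silence upstream (a configurable
label-to-silence mapping is available); filled pauses such as `<uhm>` are
speech, and units consisting only of filled-pause tokens are flagged for
optional downstream filtering but never filtered by default.

## 2. Transition classification

The classifier sweeps the maximal constant-activity intervals of the
two-channel timeline (speaker A only / B only / both / neither) while
tracking the floor holder:

- The floor is taken by the first speaker to speak alone; initial silence
  or initial overlap produces no transition.
- When the *other* speaker comes to speak alone, a **floor transfer** is
  emitted. Its FTO is the incoming turn's first-IPU onset minus the
  outgoing turn's last-IPU offset: positive = gap, negative =
  between-overlap, zero (latching) = gap.
- A maximal overlap interval after which the floor holder again speaks
  alone is a **within-overlap**: an event, not a transfer. Its duration
  and label are those of the embedded vocalisation.
- A "neither" interval flanked by the same speaker is a within-speaker
  pause, not a transition.

Degenerate configurations get deterministic tie-breaks: if both parties
stop simultaneously, the previous floor holder keeps the floor until
someone speaks alone; if the *other* speaker then resumes
(A → both → neither → B), the chain is one floor transfer whose FTO is
measured on turn boundaries and can be negative even though joint silence
intervened. An interlocutor vocalisation falling entirely inside the
floor holder's silent pause involves no overlapping speech and therefore
counts as two genuine floor transfers (a short turn "in the clear");
users who wish to exclude such free-standing backchannels can filter on
the backchannel lexicon. An overlap at the very end of a dialogue that is
never followed by anyone speaking alone is resolved as a within-overlap
(no change of speaker occurred).

Floor transfers are indexed consecutively from 1 per dialogue;
within-overlaps are unindexed. The whole classifier is checked for exact
agreement against an independent 1 ms-grid brute-force floor tracker on
1000 randomised dialogues engineered to hit the tie-break cases.

Within-overlap profiling marks events as backchannels by case-insensitive
whole-label match after punctuation stripping against a configurable
lexicon (default: mhm, mmhm, hm, mm, ja, okay, ok, genau, yeah, right).

## 3. Dialogue stages

The first Mismatch's detection time splits a dialogue into *beginning*
and *remainder*; adding the resolution time yields the three-way split
(before detection / during discussion / after resolution). A transition
is located by its anchor — the incoming turn's onset — and boundary ties
go to the later epoch. Marks are metadata; no lexical detection of the
Mismatch discussion is attempted. When a resolution time is absent only
two-way labels are produced.

## 4. Descriptive statistics

Cell summaries report n, arithmetic mean, sample SD (n − 1), median
(mean of the central pair for even n), and the modal histogram bin.
Histograms use centred half-open bins `[c − w/2, c + w/2)` with centres
on integer multiples of the width (default 100 ms), so "modal value
200 ms" refers to the bin [150, 250) and a mode at 0 is representable
symmetrically; ties return the lowest centre, flagged. Bin alignment is a
declared convention — edge-aligned bins would shift modal labels by half
a bin. The FTO-by-index curves average per floor-transfer index over the
dialogues that reach that index; smoothing is a centred moving average
with window truncation at the edges (a deliberate, simpler stand-in for
LOESS). Leave-one-dyad-out recomputes group summaries with each dyad
omitted and reports the largest absolute change in a group mean.

## 5. Hierarchical Gaussian model

Cell-means parameterisation over Group × Stage with dyad random
intercepts:

    fto_i ~ Normal(mu[cell_i] + u[dyad_i], sigma)
    u_d   ~ Normal(0, tau)
    mu_c  ~ Normal(0, 1000 ms)
    sigma, tau ~ HalfNormal(1000 ms)

Cell means (rather than treatment coding) make the per-stage group
contrasts direct differences of cells; contrasts are reported as
δ = CTR − ASD (ASD as reference level) with the posterior mean,
equal-tailed 95% credible interval, and P(δ > 0) as the fraction of
positive draws. The 1000 ms prior scales are weakly informative on the
FTO scale, where magnitudes rarely exceed ~3000 ms; all scales are
configurable.

Inference is an in-package blocked Gibbs sampler: the normal full
conditionals for `mu` (jointly) and `u` (jointly) are conjugate given the
variance components; `sigma` and `tau` take one-dimensional slice steps
(stepping-out/shrinkage, width 0.5) on the log scale against their
half-normal priors, with the relevant sums of squares computed once per
update so slice evaluations are O(1). Because the likelihood only
identifies `mu + mean(u)` within a group, a parameter-expansion sweep
step follows each cycle: for each group, a translation δ_g moving mass
between the group's cell means and its dyad intercepts is drawn from its
(Gaussian) full conditional and applied. This leaves the posterior
invariant and removes the translation ridge that otherwise cripples
mixing (split R-hat drops from ~1.17 to ~1.001 on corpus-sized fits).
Defaults are 4 chains × 4000 iterations with 2000 warm-up, per-chain RNGs
spawned from one seed. Any split rank-normalised R-hat above 1.01 raises
a warning with the full diagnostic table (R-hat and ESS via arviz).

Validation: exact agreement with the conjugate closed form in the
known-variance, no-random-effect reduction; prior recovery at zero
observations; seed-exact reproducibility; invariance to dyad relabelling;
and a calibration study — with truths drawn from the model's own priors,
the 95% credible interval for the group contrast covers the truth 95% ±
4 points over 200 scaled-down fits (2 chains × 700 iterations, 48
observations each; small fits keep the full study within seconds).
Posterior predictive checks re-simulate the data from random posterior
draws and compare replicated means/SDs with the observed ones.

## 6. Synthetic dialogue generator

The generator emits two-channel dialogue records plus a ground-truth
transition list, constructed so the classifier recovers every intended
event exactly — the identity that licenses using synthetic corpora to
validate the rest of the pipeline.

**Skeleton.** Turns alternate. A turn is a geometric number of IPUs
(mean 2.5) with lognormal durations (median 900 ms, σ = 0.55) separated
by within-speaker pauses of 200 ms plus a lognormal excess (median
120 ms, σ = 0.6); these sizes give ~3.5 s per floor transfer, matching
corpora in which dialogues of ~400 transfers run ~20 minutes. The next
turn is placed at the outgoing turn's final offset plus a sampled FTO.
Construction guarantees canonical channels: when a sampled FTO would
breach an invariant (overlap running past the outgoing turn's final IPU,
or a sub-threshold pause in the incoming speaker's channel), the outgoing
final IPU is extended just enough — FTO values are never altered, so the
calibration targets are exact at the cost of a slightly distorted IPU
duration tail.

**FTO mixture.** Per group × stage cell, FTO is negative with
probability 0.28 (lognormal magnitude) and otherwise a positive
lognormal gap. The four cells are solved analytically to match the
study's reported means and SDs exactly (ASD 511/799 beginning, 299/576
remainder; CTR 191/530 beginning, 243/558 remainder; cross-checked by
quadrature). For the remainder cells — ~90% of transfers, which dominate
the pooled distributions — the gap body's density peak is pinned at
165 ms, the value that maximises the pooled 200 ms bin's margin over its
neighbours in closed form (the binned mode of a skewed lognormal sits
right of its density peak). The beginning cells reuse their group's
overlap component and are moment-matched with a free mode: a
zero-location lognormal cannot hold a ~200 ms mode at a 511 ms mean
without inflating the SD far beyond 799 ms, and the published modal-bin
observation concerns the pooled distributions.

**Dyad heterogeneity.** Each dyad draws a mean shift (Normal, SD 90 ms).
The shift is realised by re-spreading the gap lognormal around its fixed
mode — moving the dyad's mean by exactly the drawn amount through the
tail — rather than by translating the distribution: translation moves
each dyad's peak bodily, and with only 7 dyads per group the pooled
modal bin then flips between 100 and 200 ms from seed to seed, which is
not how real dyads behave (dyad means span hundreds of ms while nearly
all dyad modes stay at 200 ms). Realised shifts are centred within each
group so that group means stay identified at small dyad counts; the
hierarchical model still sees genuine between-dyad variance.

**Within-overlaps.** Inserted per turn at a Poisson rate of 0.195 (the
within-overlap share of all transitions), with lognormal durations
(mean 380 ms, σ = 0.45) and backchannel labels with probability 0.70.
Events are placed strictly inside a host IPU with a 60 ms margin and at
least 200 ms + margin clearance from every other vocalisation of the
embedded speaker; a duration that fits no host IPU in its turn is carried
forward to that speaker's next turn, so censoring of long events (which
would bias the measured mean duration) is limited to end-of-dialogue
leftovers.

**Epoch marks.** Stages are assigned by transfer count — the first 9.5%
of floor transfers are "beginning", matching the reported average
detection at transition ~38 of ~400 (and, since transfer density is
near-uniform in time, ~10% of dialogue duration); resolution sits at
22.5% (transition ~90). Marks are placed midway between the neighbouring
anchors, so assignment by timestamp reproduces the generation-time stages
exactly. Dialogues default to 400 transfers on average (SD 40).

**What the generator does not emulate.** Real lexical content; prosody;
convergence dynamics within a stage (the beginning/remainder contrast is
a step, not a decay, so FTO-by-index curves drop at the detection index
rather than declining smoothly); annotation errors and boundary jitter;
in-the-clear backchannels (all inserted backchannels overlap speech); and
dyad-specific overlap rates. Passing the recovery tests therefore shows
the *pipeline* is correct and well calibrated, not that the generative
family matches real conversational microstructure.

## 7. Problem sizes and tolerances

The acceptance computation simulates 7 dyads per group × 20 task
dialogues (≈134k floor transfers, ≈6400 per beginning cell), a size at
which the Monte-Carlo SD of the beginning-stage group difference is
≈14 ms; the run, including the 4 × 4000 model fit, takes about a minute
on one CPU. The test suite uses the same corpus once per session and
completes in a few minutes. Disk round-trips preserve times to 10⁻⁶ s;
FTOs are rounded to integer milliseconds only in written tables and kept
unrounded in memory.
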