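# turntaking

Turn-timing analysis for dyadic dialogue: from dual-speaker
interpausal-unit (IPU) annotations to Floor Transfer Offset (FTO)
distributions, dialogue-stage contrasts, and Bayesian hierarchical group
comparisons — plus a seeded synthetic dialogue generator so the whole
pipeline can be exercised and validated without recordings.

## The problem

Conversation runs on remarkably tight timing: across languages, the modal
silence between one speaker stopping and the next starting is about
200 ms. Clinical conversation research asks whether this machinery works
differently in particular populations — here, dialogues between pairs of
autistic adults (ASD dyads) compared with pairs of non-autistic adults
(CTR dyads) solving a collaborative Map Task, where deliberately
mismatching landmarks create a discussion whose first *detection* splits
each dialogue into a *beginning* and a *remainder* stage.

The quantities of interest:

- **IPU** — one speaker's continuous vocalisation, bounded by silences of
  at least 200 ms (shorter silences are interior to the unit).
- **FTO** — at a change of speaker (a *floor transfer*), the signed offset
  `onset(incoming turn) − offset(outgoing turn)` in ms. Positive FTOs are
  silent **gaps**, negative FTOs are **between-overlaps**; FTO = 0
  (latching) counts as a gap.
- **Within-overlap** — an interlocutor vocalisation (usually a
  backchannel such as "mhm") embedded in an ongoing turn with no change
  of speaker; excluded from timing statistics.
- The group analysis is a Bayesian hierarchical Gaussian model
  `FTO ~ Group × Stage + (1 | Dyad)` in cell-means form, with
  zero-centred weakly informative priors, reporting per-stage group
  contrasts δ = CTR − ASD as posterior means, equal-tailed 95% credible
  intervals, and P(δ > 0).

## Worked example

Simulate a calibrated corpus (7 dyads per group, 4 task dialogues each),
run the pipeline, and fit the group × stage model:

```python
import turntaking as tk
from turntaking import hier_model as hm

params = tk.default_params()                # calibrated cell distributions
corpus = tk.simulate_corpus(params, n_dyads_per_group=7,
                            dialogues_per_dyad=4, seed=11)
analysed = tk.analyse_corpus([rec for rec, _truth in corpus])
transfers = tk.transfers_frame(analysed)    # one row per floor transfer

print(tk.corpus_accounting(analysed).to_dict())
print(tk.summarise(transfers, "group_stage").round(1))

draws = hm.fit(transfers,
               hm.ModelSpec(chains=4, iterations=2000, warmup=1000, seed=5),
               stage_col="epoch2")
for stage in ("beginning", "remainder"):
    _, s = hm.group_contrast_by_stage(draws, stage)
    print(f"{s.name}: mean {s.mean_ms:.0f} ms, "
          f"95% CI [{s.ci_low_ms:.0f}, {s.ci_high_ms:.0f}], "
          f"P(delta>0) = {s.p_gt_zero:.2f}")
```

Output (abridged):

```
{'n_gap': 16130, 'n_between_overlap': 6377, 'n_within_overlap': 4443,
 'n_total': 26950, 'n_timing': 22507, 'gap_share_timing': 0.717, ...}

group    epoch2     n  mean_ms  sd_ms  median_ms  modal_bin_ms
  ASD beginning  1067    477.5  736.3      392.3        -100.0
  ASD remainder 10450    301.0  640.3      219.8         200.0
  CTR beginning  1016    204.0  709.0      159.2         100.0
  CTR remainder  9974    244.0  564.0      210.1         200.0

CTR-ASD @ beginning: mean -275 ms, 95% CI [-377, -173], P(delta>0) = 0.00
CTR-ASD @ remainder: mean -58 ms, 95% CI [-151, 30], P(delta>0) = 0.09
```

Reading it: about 72% of floor transfers are gaps and 28% overlaps; both
groups' pooled FTO distributions peak in the 200 ms bin; the ASD dyads
start out with much longer gaps (beginning-stage mean ≈ 480 ms vs
≈ 200 ms for CTR, a contrast of roughly −280 ms with all posterior mass
below zero at this corpus size), while in the remainder of the dialogue
the groups are statistically indistinguishable (CI spans zero).

The same steps are scriptable from the shell:

```bash
ttk simulate --dyads 7 --seed 11 --out corpus/
ttk analyze --table corpus/ASD01-t1.tsv --table ... --out analysis/
ttk fit --transitions analysis/transitions.tsv --model group_x_stage2 \
    --seed 5 --out fit.json
ttk report --transitions analysis/transitions.tsv --out figures/
```

## Reading real annotations

`annotation_io` ingests Praat TextGrids (long or short dialect, UTF-8 or
UTF-16, one interval tier per speaker; empty-label intervals are silence)
or flat delimited tables with `speaker/start/end/label` columns, plus a
YAML sidecar with dyad ID, group label, and the Mismatch detection /
resolution timestamps. Both routes produce identical in-memory records.
Filled pauses (`<uhm>`) count as speech and are flagged, never dropped.

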