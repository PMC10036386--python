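# del22q

Analysis toolkit for cell-free DNA (cfDNA) prenatal screening of
**22q11.2 deletion syndrome** (DiGeorge / velocardiofacial syndrome).

Maternal plasma cfDNA is a mixture of maternal and placental ("fetal")
fragments; massively parallel sequencing groups it into 50-kb bins and a
22q11.2 deletion shows up as a depressed read depth over the deleted
interval. Because the deletion can live in the fetus, in the pregnant
patient, or in both, and because its breakpoints fall between four
low-copy-repeat blocks (LCR22 A–D), a screen-positive result raises
concrete follow-up questions: *is the event maternal or fetal? how big
is it? will standard FISH probes even see it? and what positive
predictive value should be quoted when many screen positives never get
complete diagnostic testing?*

`del22q` implements that whole analysis loop as a tested library:

- **`regions`** — the 22q11.2 coordinate model: LCR22 A–D blocks, FISH
  probe targets (N25, TUPLE1/HIRA, TBX1), a 50-kb bin grid, BED I/O.
- **`simulate`** — a maternal-plasma mixture simulator. Inside a deleted
  interval the expected depth ratio is `1 − c/2`, with carrier fraction
  `c = ff` (fetal event), `1 − ff` (maternal, not transmitted), `1`
  (maternal, transmitted); bin counts are Poisson (negative binomial via
  a dispersion knob).
- **`caller`** — `DeletionCaller`, a scikit-learn-style estimator:
  `fit` on a reference panel of unaffected samples, `predict` deletion
  calls (interval, z-score, event fraction ε = 2(1 − r), size quantized
  to whole bins).
- **`origin`** — the mosaicism ratio MR = ε / ff and the
  `OriginClassifier`: MR > 3 ⇒ *likely maternal*, else *suspected
  fetal*. Analytically MR ≈ 1 for fetal events, (1 − ff)/ff or 1/ff for
  maternal ones.
- **`fish`** — probe-overlap logic: nested deletions distal to the A–B
  interval escape all standard FISH probes, so microarray is always
  recommended first.
- **`stats`** — five PPV accounting scenarios with Wilson confidence
  intervals, Wilcoxon rank-sum (exact under ties for small samples),
  Fisher's exact test, and size-concordance regression.
- **`fixture`** — a deterministic 307-case screen-positive cohort
  reconstructing the dispositions of a published single-laboratory
  clinical series, used to reproduce its printed numbers exactly.
- **`pipeline` / `cli`** — end-to-end runs (`simulate → call → classify
  → advise → stats`) with full seed determinism, and a `del22q` console
  script.

## Worked example

Classify a called event with event fraction 0.93 at fetal fraction 11%:

```bash
$ del22q classify --epsilon 0.93 --ff 0.11
{"cutoff": 3.0, "mr": 8.454545454545455, "origin_call": "likely_maternal"}
```

The MR of 8.45 is far above the cutoff of 3: the depth depression is
much too deep to be explained by an 11% fetal compartment, so the
deletion is almost certainly carried by the pregnant patient (a
confirmed maternal deletion implies a 50% transmission risk to the
fetus, so maternal testing is advised).

Ask whether FISH would confirm a distal nested (C–D) deletion:

```bash
$ del22q advise --start 20950000 --end 21500000
{"fish_sufficient": false, "maternal_testing_advised": false,
 "probe_detectable": {"N25": false, "TBX1": false, "TUPLE1_HIRA": false},
 "recommended_assays": ["microarray"]}
```

All three standard probes hybridize between LCR22A and LCR22B, proximal
to this interval — FISH would return a false-normal result, so only
microarray is recommended.

Recompute the published cohort numbers from the deterministic fixture:

```bash
$ del22q reproduce
                 quantity  computed  expected  pass
             ppv_complete      99.4      99.4  True
           ppv_fetal_only      98.7      98.7  True
         ppv_conservative      90.7      90.7  True
          ppv_upper_bound      99.7      99.7  True
          ppv_lower_bound      57.3      57.3  True
   ...
```

The spread 57.3–99.7% is the same cohort under different accounting of
unverified cases: 99.4% counts only the 177 completely tested cases
(176 true positives, 1 false positive), 90.7% treats the 17
incompletely tested cases as hypothetical false positives, and the
bounds assign all 130 unverified cases one way or the other.

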