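# seamount-ebsa

Scoring framework for seamount conservation assessment: how likely an
individual seamount is to qualify as an **Ecologically or Biologically
Significant Area** (EBSA) under the Convention on Biological Diversity
criteria, how severely it is threatened by fishing and mining, how
trustworthy the underlying evidence is, and which conservation-portfolio
category it belongs to.  It is aimed at marine spatial planners and
deep-sea ecologists who need to rank candidate features from the sparse,
presence/absence-grade information that actually exists for most
seamounts.

## The model

**EBSA likelihood.**  Ten weighted indicator slots proxy the seven CBD
criteria — four benthic indicators of weight 3 (vent communities,
macrophytes, cold-water corals, sponge aggregations), aggregating deep-sea
fishes (2), threatened bottom fishes (1), two pelagic OR-pairs scored
either as a threatened variant (2) or a plain variant (1), naturalness (1)
and shallow summit depth (1).  With `W` the weight sum of the indicators
present and `W_max = 21`,

    S = 1 + 4 W / W_max  ∈ [1, 5],    low if S ≤ 3, high if S > 3.

**Threat score.**  Nine human activities (eight fishing gears plus
seafloor mineral extraction) carry integer impact ratings 1–5 against five
ecological groups (physical habitat, corals & sponges, groundfish, large
pelagics, air-breathing visitors).  A seamount's threat score is the mean
over the groups of the maximum rating among its present activities:

    TS = mean_g  max_{a present} M[a, g],    none TS = 1, low ≤ 3, high > 3.

The rating matrix `M` is not published as numbers, so the package
reconstructs a canonical one with an exact constraint solver
(`fit_impact_matrix`) from the scores the original assessment prints.

**Data uncertainty.**  Every scored observation has an evidence grade
(high 0, medium 0.5, low 1); `U = mean grade weight + fraction of
data-deficient slots` ∈ [0, 2] is drawn as a symmetric error bar
`score ± U`.

**Portfolio.**  Crossing low/high EBSA with low/high threat yields four
cells that map onto different management strategies (protect pristine
sites vs. close impacted sites for recovery).

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

The eight case-study seamounts (six Atlantic, two Gulf of Alaska) ship as
packaged fixtures:

```bash
python examples/score_case_studies.py
```

```text
seamount      EBSA   +/-   cat threat   +/-   cat  portfolio
Sedlo         3.86  0.25  high   2.60  0.28   low  highE_lowT
Condor        3.48  0.35  high   3.60  0.50  high  highE_highT
Rosemary      2.52  0.59   low   5.00  0.61  high  lowE_highT
Anton Dohrn   3.29  0.58  high   3.60  0.61  high  highE_highT
Josephine     3.29  0.70  high   5.00  1.17  high  highE_highT
Gorringe      3.86  0.58  high   4.60  1.34  high  highE_highT
Bowie         3.10  0.45  high   2.40  0.50   low  highE_lowT
Cobb          3.10  0.49  high   2.60  0.54   low  highE_lowT
```

Sedlo scores 3.86: a likely EBSA (its corals, sponges, aggregating fishes
and threatened pelagic visitors are present) under light pressure (only
pelagic longlining, threat 2.60) — a near-pristine conservation candidate.
Rosemary is the mirror case: low EBSA likelihood but six gear types
present (threat 5.00).  The `+/-` columns are the uncertainty indices;
Josephine's EBSA interval 2.59–3.99 spans the category boundary, flagging
it for survey work before a decision.

The same numbers are available from the CLI and as JSON/CSV:

```bash
seamount-ebsa score src/seamount_ebsa/data/case_studies.csv --out results.json
seamount-ebsa report results.json --scatter scatter.csv --radar radar.csv
```

Other examples: `reconstruct_impact_matrix.py` (the constraint solver and
the canonical gear-impact matrix), `uncertainty_error_bars.py`,
`simulate_dummy_seamounts.py` (1000 random seamounts vs. the exact
enumeration of the scoring geometry).

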