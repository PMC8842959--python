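# gebvrel

Deterministic prediction of the reliability (squared accuracy) of genomic
estimated breeding values (GEBV), viewed throughout as a proportion of
variance explained, plus two independent routes for combining information
sources — Fisher information (FI) and selection-index theory (SIT) — and a
Monte-Carlo simulator of the effective-chromosome-segments model that
validates the closed forms.

## What it computes

With phenotypic variance normalized to 1, a reference population of `N`
genotyped+phenotyped individuals, heritability `h2`, marker-captured
fraction `q2` of the genetic variance, and `Me` effective segments:

* **Single-population reliability** at three levels of approximation:
  single-segment R² (exact and approximate), and the joint-fit form that
  accounts for the residual-variance reduction from fitting all segments
  simultaneously (a quadratic in r², solved in closed form or by fixed
  point). The marker information amount is `theta = N*q2*h2/Me`.
* **Combining sources.** Reliabilities convert to information amounts and
  back; amounts sum across sources with independent sampling errors, but
  only when they target the same genetic component (marker-captured vs.
  full genetic) — mixing components is refused. The SIT closed-form merges
  and a general selection-index solver reproduce the FI results exactly
  when the residual variance is treated the same way; both a
  frozen-residual and a residual-reduction variant are exposed, since
  whether the reduction applies when merging pedigree and genomic data is
  an open modelling question.
* **Monte-Carlo validation.** Independent, equal-variance segment scores;
  ridge/BLUP fitting of segment effects; reliability measured as squared
  out-of-sample correlation between GEBV and the true genetic value.

## CLI

```sh
# all deterministic routes for one parameter set
gebvrel predict --n 5000 --h2 0.3 --q2 0.8 --me 400
# or supply the information amount directly
gebvrel predict --theta 0.75 --h2 0.3 --q2 0.8

# merge two subpopulation reliabilities (frozen residual vs full reduction)
gebvrel combine --mode subpops --r2 0.3658 --r2 0.3658 \
    --h2 0.3 --q2 0.8 --me 400 --residual reduced
# merge pedigree + genomic; --engine index routes through the
# selection-index solver as a cross-check of the closed forms
gebvrel combine --mode pedigree-genomic --r2 0.6297 --r2 0.6297 --h2 0.3

# Monte-Carlo check of the deterministic prediction
gebvrel simulate --n 2000 --me 400 --h2 0.3 --q2 0.8 --reps 30 --seed 1

# reproduce the two reference worked examples (non-zero exit on mismatch)
gebvrel examples

# run every route over a TSV/CSV parameter table (columns N, h2, q2, Me)
gebvrel grid params.tsv --out results.tsv
```

Parameters can also come from a YAML/JSON file via `--config`; explicit
flags win.

Note on the first worked example: its printed per-subpopulation
information amount (0.75) corresponds to `N*h2/Me` rather than
`N*q2*h2/Me` (= 0.6) for the stated inputs. The examples runner uses the
printed 0.75 as given; `theta` can always be supplied directly to bypass
the formula.

## Layout

| module | contents |
| --- | --- |
| `gebvrel.predict_core` | parameter types, single-population closed forms |
| `gebvrel.info_combining` | information algebra, SIT merge formulas |
| `gebvrel.selection_index` | general index solver (independent derivation route) |
| `gebvrel.validation_sim` | segments-model simulator and ridge/BLUP fit |
| `gebvrel.reporting` / `gebvrel.cli` | worked examples, grid runner, CLI |
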