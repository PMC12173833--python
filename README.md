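# tedyn

Transposable-element (TE) insertion-time landscapes and phylogenetic
comparative statistics for pollinating and non-pollinating fig wasps
(NPFWs), packaged as a tested, reusable pipeline.

Pollinating fig wasps complete their life cycle inside the enclosed fig
syconium; most NPFWs oviposit from outside through the fig wall. This
ecological split leaves a genomic signature: NPFW genomes carry far more
TE sequence, more TE copies and more TE families, with recent
"aggressive" insertion bursts, while pollinator genomes show "dormant"
landscapes dominated by old, decayed copies. `tedyn` implements the
quantitative toolkit behind that comparison:

- **Insertion-time dating.** Each annotated TE copy carries a percent
  divergence *D* from its family consensus (RepeatMasker `.out`). The
  multiple-hit correction `K = -(300/4) ln(1 - 4D/300)` and the molecular
  clock `T = K / 2r` (with *r* the per-site substitution rate in
  substitutions/site/My, calibrated from a root-to-tip path and a fossil
  date) turn the divergence spectrum into an age landscape; binning total
  copy length by age exposes burst peaks and window loads (e.g. the
  fraction of TE length younger than 5 My).
- **Phylogenetic signal.** Blomberg's *K* for continuous traits (K ≈ 1
  under Brownian motion) with a tip-permutation test, the Fritz–Purvis
  *D* statistic for binary traits (D ≈ 1 random, ≈ 0 Brownian, strongly
  negative for clade-aggregated traits such as oviposition site), and a
  Monte-Carlo power analysis of the *K* test on a given tree.
- **PGLS.** Phylogenetic generalized least squares with Pagel's λ
  (profile ML or fixed), AICc model comparison, and Brownian ancestral
  state reconstruction — the machinery for asking whether TE load tracks
  genome size, oviposition site, or both.
- **Group statistics.** Exact Mann–Whitney *U* (tie-aware, complete
  enumeration of group assignments for the two-sided p), one-sample *t*
  with CI / Cohen's d / relative elevation, and one-way ANOVA with Tukey
  HSD compact letters.
- **Genomic context.** TEs within 1 kb of gene sets (with
  consensus-normalized lengths), three-way TE/CRM (cis-regulatory
  module) overlap classification, and genome-window density tracks.
- **Synthetic data.** Every input can be generated with known ground
  truth: TE copies from dated insertion bursts (exact algebraic inverse
  of the dating correction), Yule trees, Brownian and clumped binary
  traits, and planted gene/TE/CRM interval sets with a truth ledger.

The package ships the 11-species fig-wasp trait table (6 pollinators, 5
NPFWs: genome size, TE length/count/family count/content, substitution
rate, oviposition site) so every desk-scale group statistic is
reproducible offline.

## Worked example

Reproduce the published group statistics from the packaged trait table:

```sh
$ tedyn reproduce
```

prints, among others (stderr table; JSON on stdout):

```
te_length          U          computed=28         published=28       PASS
te_length          Z          computed=2.373      published=2.373    PASS
te_length          p_exact    computed=0.01732    published=0.017    PASS
benjamina_ttest    t          computed=4.758      published=4.758    PASS
```

TE length is significantly higher in NPFWs than pollinators (U = 28 of a
possible 30, tie-corrected Z = 2.373, exact two-sided p = 0.017), and
within the single shared host fig the three NPFW species carry a 135%
elevated TE content relative to their pollinator (t = 4.758, df = 2).

Date a synthetic insertion burst and recover it from the landscape:

```sh
$ tedyn simulate te-out --seed 11 --n-copies 2000 --age-mean 20 --age-sd 2 \
      --rate 0.0049 --out demo.out
$ tedyn landscape --rm-out demo.out --rate 0.0049 --windows 10:30,0:5 --out demo
{
  "rate_r": 0.0049,
  "total_mass_bp": 1002224.0,
  "window_fractions": {
    "10.0-30.0": 1.0,
    "0.0-5.0": 0.0
  },
  "peaks_mya": [ [ 17.0, 22.0 ] ]
}
```

The planted burst at 20 My is recovered as a single peak spanning 17–22
My, all of its mass falls in the 10–30 My window, and the landscape's
total mass equals the summed copy length of the input exactly.

## Layout

```
src/tedyn/
  io_formats.py       RepeatMasker .out / BED / GFF3 / newick / trait-table IO
  synthetic_data.py   ground-truth generators (bursts, trees, traits, intervals)
  te_landscape.py     divergence correction, dating, landscapes, peaks
  phylo_signal.py     Blomberg's K, Fritz–Purvis D, power analysis
  pgls.py             PGLS with Pagel's lambda, AICc, ancestral states
  group_stats.py      exact Mann–Whitney, one-sample t, ANOVA + Tukey
  genomic_context.py  gene proximity, TE/CRM overlap, window densities
  cli_report.py       `tedyn` CLI and the reproduction report
```

See `docs/methods.md` for the statistical details and design choices.
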