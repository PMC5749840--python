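# lomaspulse

Community-dynamics analysis for repeated vegetation surveys on a fixed plot
panel: per-plot and per-campaign diversity metrics, an importance value
index, a seasonality index with stabilization detection, Spearman climate
screens with Bonferroni correction, all-pairs paired-t campaign comparisons,
Kruskal–Wallis zone tests, and a from-scratch detrended correspondence
analysis (CA + rare-species downweighting + detrending by segments).  A
synthetic survey generator with serialized ground truth makes every stage
testable at desk scale.

## Input formats

* **Survey CSV** (long format, UTF-8, comma-delimited):
  `campaign_id,date,plot_id,zone,species,abundance,cover_cm2` — one row per
  (campaign, plot, species) with ≥ 1 individual; `date` is `YYYY-MM`;
  `zone` ∈ {low, medium, high}. Plots with no records in a campaign are
  carried by the plot roster and count as empty (zeros) in all statistics.
* **Climate CSV**: `month,precip_mm,temp_c` with `month` as `YYYY-MM`.

Campaigns whose absolute cover is known to be overestimated can be flagged
(`--flag-cover Feb-98,Aug-98`); flagged campaigns are excluded from
absolute-cover statistics but retained wherever cover enters only as a
relative value (the importance value index).

## CLI

```sh
lomaspulse simulate  --seed 1 --out-prefix sim            # synthetic data
lomaspulse metrics   --survey sim_survey.csv --out summary.tsv
lomaspulse ivi       --survey sim_survey.csv --out ivi.tsv
lomaspulse dca       --survey sim_survey.csv --out-prefix dca
lomaspulse correlate --survey sim_survey.csv --climate sim_climate.csv --out-prefix corr
lomaspulse compare   --survey sim_survey.csv --out-prefix pairwise
lomaspulse run-all   --survey sim_survey.csv --climate sim_climate.csv \
                     --flag-cover Feb-98,Aug-98 --out results/
```

`run-all` writes every table (TSV) plus `summary.json`; outputs are
byte-stable for a fixed input and configuration.

## Layout

```
src/lomaspulse/
  survey_io.py            # readers/writers, validation, cover flags
  community_metrics.py    # density, cover, Shannon alpha/gamma, richness, IVI
  seasonality.py          # seasonality index, stabilization detection
  climate_association.py  # Spearman screens + Bonferroni families
  group_comparisons.py    # paired t (all pairs), Kruskal–Wallis, letters
  ordination.py           # CA, downweighting, detrending-by-segments, DCA
  synthetic_data.py       # simulator + ground truth, small fixture
  pipeline.py, cli.py     # orchestration and command line
  study.py                # conventions for the original dataset
```
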