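# ntlimpact

Epidemic impact and recovery analysis from daily nighttime-light (NTL)
rasters.

Daily low-light satellite imagery (nW/cm²/sr on an equal-area 500 m grid) is
a direct proxy for human activity: when a lockdown empties a city, its
lights dim; when field hospitals and checkpoints light up, a few pixels
brighten. `ntlimpact` turns that signal into a tested analysis pipeline for
epidemiologists and remote-sensing analysts who want to quantify, per city,
how strongly an outbreak suppressed activity and how completely activity
recovered — without waiting for official statistics.

## The method

For each pixel *i* on a shared grid:

* **Cleaning.** Negative radiances are clamped to 0; dates contaminated by
  moonlight are dropped (explicit windows around new moons, or a lunar
  phase-angle criterion); per-pixel time-series outliers are repaired with
  Tukey quartile fences: values above `Q3 + 1.5·IQR` (fires, scan-edge
  noise) are clipped to that fence, values below `Q1 − 1.5·IQR` (cloud) to
  the lower fence.
* **Change.** `CNTL_i = R_i − r_i − D_i`, where `R_i` is the mean retained
  outbreak-period radiance, `r_i` the lunar-calendar-matched previous-year
  baseline (matched dates sit at the same displacement from the Chinese New
  Year, so Spring-Festival effects cancel), and the development index
  `D_i = d_i − d'_i` removes secular year-over-year growth.  Pixels with
  `CNTL < −1` are *decrease*, `> 3` *increase*, else background.
* **Intensity.** Per city, `SCNTL = Σ CNTL_i` over affected pixels; cities
  are graded into five severity levels (I worst … V) by Jenks natural
  breaks, and typed into HH/HL/LH/LL spatial clusters with the Anselin
  Local Moran's I under inverse-distance weights and conditional
  permutation inference.
* **Recovery.** `RNTL = Σ R'_i / Σ r'_i` over a recovery window and its
  matched baseline window; `RNTL ≥ 1` means fully recovered.  The mobility
  cross-check is `m = P_j / p_j` from intra-city travel-intensity indices,
  compared to RNTL in a banded cross-tabulation.  The D-value
  `RNTL_Mar − RNTL_Feb` flags relapsing cities.
* **Trends.** Per city, daily sums of (current − baseline) radiance over
  the decrease/increase masks are fitted with fifth-order polynomials
  (D-line / I-line); two interior D-line maxima ⇒ an "M-type" city (two
  recovery phases), one ⇒ "inverted-U"; the D-line's end slope (tail up /
  down) signals further recovery or relapse.

Every stage is exercisable end to end on seeded synthetic scenes with
planted ground truth (bright CBD cores with exponential decay, dark pixels
fluctuating in 0–1, sparse spikes outnumbering cloud drops, per-zone
suppression profiles, case tables, mobility series).

## Worked example

```sh
ntlimpact run-all --seed 1 --out out/
```

simulates a six-city scene (100×100 grid, 20 Jan – 31 Mar daily layers),
cleans it, and prints the per-city severity table:

```
pipeline complete; products in out/
 zone_id        scntl  level
       1 -1930.935695      2
       2 -2398.128905      1
       3 -1770.791954      3
       4  -278.905653      4
       5  -183.170105      4
       6    20.278043      5
```

`scntl` is each city's summed radiance change (nW/cm²/sr) over its affected
pixels — more negative means more suppressed activity — and `level` is the
five-band natural-breaks grade.  Zones 1–3 were planted with the deepest
suppression (dimming to 35–60 % of baseline), zones 5–6 the shallowest, and
the grading recovers that ordering; zone 6's slight net increase is its
planted hospital-pixel brightening outweighing a mild dimming.  `out/` also contains the change raster and class
map (GeoTIFF), affected areas, Moran cluster types, February/March recovery
degrees with the mobility cross-tab, fitted trend lines, and a run manifest.

The same stages are available as library functions (`smbq_repair`, `cntl`,
`scntl`, `jenks_breaks`, `local_moran`, `rntl`, `zone_trends`, …) on plain
numpy arrays and pandas tables.

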