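# planwatch

Vendor-independent automatic evaluation of external-beam breast
radiotherapy plans:

- **DVH engine** — cumulative dose-volume histograms computed from DICOM-RT
  first principles (RTDOSE grid + RTSTRUCT contours, even-odd
  point-in-polygon with per-axis supersampling), or read from tabular
  cumulative-DVH CSV exports. Metrics are named by a small grammar
  (`V16Gy[%]`, `D95%[Gy]`, `Dmean[Gy]`, ...).
- **Protocol checking** — editable text protocol files (RTOG1005,
  FAST_FORWARD, FAST, EUROPA_PBI, EUROPA_WBI) with automatic selection by
  dose-per-fraction / fraction count / PTV kinds; traffic-light statuses
  (green / yellow / red, starred "extra" tier) and a protocol-fulfilment
  score `bw_score` = percent of evaluated PTV + Main-OAR constraints whose
  mandatory limit is met (yellow counts as fulfilled).
- **Community plan library** — append/load/filter a CSV library of
  exported plan records; per-metric community percentile score
  `cb_score` = floor of the integer percent of similar library plans with
  strictly worse values; inspector statistics (min/max/mean/SD,
  histogram, above-mean flags).
- **Plan sanity check** — isocenter count, MU-Sum range, dose-rate set,
  IMRT/VMAT jaw-X width, setup-beam couch rotation (all thresholds
  site-configurable), plus an MU-Sum community inspector.
- **Change detection** — chronological series split into BEFORE/AFTER
  groups; one-tailed Mann-Whitney-Wilcoxon U-tests on raw values and on
  squared deviations from the group mean (`qdev`).
- **Synthetic generators** — box phantoms written as real DICOM-RT
  triplets with analytically exact metric tables, and seeded community
  libraries with specified distributions. The whole pipeline is testable
  without clinical data.

DICOM I/O is self-contained (`planwatch._dicomlite`, Explicit VR Little
Endian only); no external DICOM library is required.

## CLI

```sh
# generate demo fixtures
planwatch make-phantom --out demo_plan
planwatch make-library --out library.csv --n 50 --seed 1

# evaluate a plan (exit 0 = all mandatory limits met and sanity PASS)
planwatch evaluate --dicom-dir demo_plan --library library.csv --export --user alice
planwatch evaluate --dvh-table dvh.csv --prescription-gy 26 --fractions 5 --json

# community inspector for one metric
planwatch inspect --library library.csv --metric 'LUNG_IPSI:V16Gy[%]' \
    --value 15 --protocol FAST_FORWARD --laterality RIGHT --technique VMAT

# plan sanity check (+ MU-Sum community comparison)
planwatch sanity --dicom-dir demo_plan --library library.csv

# change detection on a metric's chronological series
planwatch cohort --library library.csv --metric 'HEART:Dmean[Gy]' \
    --split 34 --alternative AFTER_LOWER --protocol FAST_FORWARD
```

Structure-name matching uses an editable lexicon
(`src/planwatch/data/lexicon.txt`, `ROLE: token, token, ...` lines;
English + Italian defaults). Protocol constraint tables live in
`src/planwatch/data/protocols/*.txt` and are plain text with one
constraint per line.

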