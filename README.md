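# frapconn

Quantification of vacuole lumen connectivity from FRAP (fluorescence
recovery after photobleaching) time series, with a ground-truth simulator
for validation.

## The problem

Plant vacuoles in young root cells form thin tubular networks whose luminal
continuity cannot be resolved by light microscopy alone: structures that
look separate in a single optical section may share one lumen, and vice
versa. FRAP resolves this functionally. A laser pulse irreversibly bleaches
the fluorophore in a small vacuolar area; if the surrounding structures are
connected to it, unbleached fluorophore diffuses in and the fluorescence
recovers. The speed and completeness of that recovery report luminal
connectivity.

`frapconn` implements two complementary read-outs for microscopists working
with such time series:

**Recovery classes.** The post-bleach trace of the bleached area, normalized
to the pre-bleach mean, is fit with a single-exponential recovery

```
I(t) = I0 + (Iinf − I0) · (1 − exp(−k t)),     t½ = ln 2 / k
```

and the mobile fraction is `(Iinf − I0)/(1 − I0)`. Vacuoles are binned as
**fast** (t½ < 2 s), **medium** (2 s ≤ t½ < 5 s), **slow** (t½ ≥ 5 s), or
**no recovery** (mobile fraction < 30%, or a failed fit).

**Connectivity Index (CI).** Small, motile vacuoles in meristematic cells
fluctuate too much for curve fitting, so the CI compares only the frames
immediately before (Frame −1) and after (Frame 1) the bleach. With the
percent intensity changes ΔI of the bleached area *a*, a distant area *b*
of the same vacuole, and a control area *c* in a neighboring cell (whose
vacuole is certainly not connected):

```
Rel = ΔI_a − ΔI_b        Ref = ΔI_a − ΔI_c        CI = (Ref − Rel) / Ref
```

CI = 1 means *a* and *b* are fully connected and mix faster than the frame
rate; CI = 0 means no exchange; empirically CI < 0.1 marks disconnected
compartments. CI outside [0, 1] indicates a technical problem (usually
sample drift) and is QC-flagged rather than silently dropped.

Because live-cell FRAP data are rarely deposited, the package ships a
simulator: vacuoles are modelled as compartment networks (2D masks, volumes,
exchange conductances) whose concentrations follow the conservative linear
exchange system `dC_i/dt = (1/V_i) Σ_j k_ij (C_j − C_i)`, solved by matrix
exponential and rendered into 16-bit image series with Poisson noise and
optional drift. Graph connectivity of the network is the known ground truth
against which both read-outs are validated.

## Worked example

Simulate a constricted two-lobe vacuole (a connected chain with a
low-conductance bottleneck), then quantify it from the written TIFF:

```bash
frapconn simulate --style constricted --n-compartments 2 --n-post 60 --seed 5 --out demo
frapconn fit --series demo/series.tif --rois demo/rois.json --out demo/fits.csv
frapconn ci  --series demo/series.tif --rois demo/rois.json --out demo/ci.csv
frapconn classify --fits demo/fits.csv --out demo/classes.csv
```

which prints

```
t_half=3.04631607180419 mobile=0.4425760080106177 converged=True
ci=0.1129 qc=ok
```

and `demo/classes.csv` holds `series,3.04631607180419,0.4425760080106177,medium`.
Read-out: the bleached lobe recovers with a half-time of ≈3 s and a mobile
fraction of 44%, so it is classified **medium** — connected, but through a
bottleneck. The CI of 0.11 sits just above the 0.1 cut-off, consistent with
sluggish but real exchange: within the single frame interval the distant
lobe has barely begun to lose intensity, which is exactly the regime where
the recovery classes are the more informative read-out.

The same steps are available as library calls (`build_network`,
`simulate_concentrations`, `render_series`, `ci_from_series`,
`fit_single_exponential`, ...); the numbered scripts under `analysis/` run
the full simulated study: cohort simulation and classification
(`01_simulate_cohorts.py`), empirical cut-off calibration
(`02_calibrate_cutoff.py`), and the aggregate report with rank-sum letter
groups and zone t-tests (`03_report.py`), writing tables under `results/`.

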