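# gshquant

Quantitative analysis toolkit for reversible, ratiometric small-molecule
glutathione (GSH) sensing — the measurement framework behind
Michael-addition probes whose 405/488-nm excitation ratio reads out
intracellular GSH in the physiological 1–10 mM range.

GSH is the most abundant non-protein thiol in eukaryotic cells. A
reversible Michael-acceptor probe P binds GSH to form an adduct A with a
millimolar dissociation constant,

```
P + GSH ⇌ A        Kd = [P][GSH]/[A]
```

and the two species dominate different excitation channels, so the
fluorescence ratio R = F405/F488 encodes the GSH concentration
independently of probe loading.  `gshquant` implements the complete
quantitative chain around this sensor:

* **binding** — the mass-action equilibrium (stable quadratic root),
  spectral ratio forward model, Kd estimation from titrations, and
  competitive partitioning among thiols (e.g. GSH vs. cysteine);
* **kinetics** — the reversible rate law dA/dt = kf(P_T−A)(G_T−A) − kr·A
  with an exact closed-form solution, observed-rate (kobs = kf·[GSH]+kr)
  fitting, and (kf, kr) recovery from trace series and
  dilution-relaxation experiments;
* **calibration** — the Grynkiewicz-style saturation calibration
  (R−Rmin)/(Rmax−R) = k·C and its inversion, with out-of-range flagging;
* **imaging** — two-channel confocal pipeline: background subtraction,
  segmentation, per-pixel ratio maps, per-cell median ratios, calibrated
  concentrations, and nearest-centroid time-lapse tracking;
* **cytometry** — scatter/singlet/4-s.d. outlier gating of event tables,
  per-sample median ratios, FACS-vs-lysate calibration and comparisons;
* **assays** — enzymatic recycling (DTNB) slope quantification, LC-MS
  NMM-adduct standard curves, and conversion to intracellular mM via
  cell volume (4,000 μm³ per HeLa/HT1080-like cell);
* **synthetic** — seeded generators for every input type with
  machine-readable ground truth.

## Worked example

Simulate a titration of 10 μM probe against 0–50 mM GSH with 1%
multiplicative readout noise, then fit the dissociation constant:

```
$ gshquant simulate --kind titration --seed 1 --out demo
$ gshquant fit-binding demo/titration.csv
kd_mM = 3.6818
kd_stderr_mM = 0.0071
n_points = 12
```

The generating constant was 3.7 mM; the fit recovers it within 0.5%.
The same workflow exists for kinetics — three pseudo-first-order traces
at post-mixing GSH 2.5/5/10 mM (probe 5 μM) are fit per-trace for kobs
and regressed against concentration:

```
$ gshquant simulate --kind kinetics --seed 2 --out demo_k
$ gshquant fit-kinetics demo_k/forward_0.csv demo_k/forward_1.csv demo_k/forward_2.csv
kf_per_M_s = 7.5804
kr_per_s = 0.020280
fold_vs_TQG = 50.54
```

i.e. a forward rate constant of ≈7.5 M⁻¹ s⁻¹ (about 50× the
first-generation probe) and a reverse rate of ≈0.020 s⁻¹.  Further
subcommands (`calibrate`, `quantify-images`, `quantify-facs`, `assay`)
run the imaging and cytometry pipelines from TIFF/CSV inputs; see
`gshquant --help`.

## Layout

```
src/gshquant/      library modules (binding, kinetics, calibration,
                   imaging, cytometry, assays, synthetic, cli)
tests/             pytest suite, including end-to-end acceptance tests
scripts/           acceptance script
docs/methods.md    model descriptions, parameter choices, limitations
```
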